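"""Treatment/receptor/cytokine link inference.

A link is a triple (treatment, receptor, cytokine) expressing that the
treatment reproducibly and strongly shifts both the receptor's expression
and the cytokine's secretion, with the receptor-cytokine relationship
consistent across treatments.  Three retention criteria are applied to
each candidate triple:

reproducibility
    The effect direction is shared by at least 3/4 of the biological
    replicates (for both the receptor and the cytokine effect).
amplitude
    The mean log2 effect lies in the upper or lower quartile of the pooled
    per-(treatment, readout) mean effects of the same readout kind.
coherence
    Across the treatments where both effects are informative, the
    receptor-cytokine sign product is constant: the pair is always
    correlated, or always anti-correlated, never a mixture.

Retained links carry the effect signs and the coherence sign and can be
assembled into a Boolean network: one input node per ligand, one AND node
per combined treatment, and per-readout update functions OR-ing the
activating treatments and excluding the inhibiting ones.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import response as rd
from .boolnet import BooleanNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateLink",
    "RetainedLink",
    "InferenceConfig",
    "enumerate_candidate_links",
    "is_reproducible",
    "passes_amplitude",
    "amplitude_cutoffs",
    "is_coherent",
    "infer_links",
    "LinkInferrer",
    "links_to_network",
    "write_links",
]


@dataclass(frozen=True, order=True)
class CandidateLink:
    treatment: str
    receptor: str
    cytokine: str


@dataclass(frozen=True, order=True)
class RetainedLink:
    """A candidate that passed all three criteria, with its signs.

    ``coherence_sign`` is +1 for an always-correlated receptor/cytokine
    pair and -1 for an always-anti-correlated one; it equals
    ``receptor_sign * cytokine_sign``.
    """

    treatment: str
    receptor: str
    receptor_sign: int
    cytokine: str
    cytokine_sign: int
    coherence_sign: int

    @property
    def candidate(self) -> CandidateLink:
        return CandidateLink(self.treatment, self.receptor, self.cytokine)


@dataclass(frozen=True)
class InferenceConfig:
    """Thresholds of the three retention criteria.

    reproducibility_fraction:
        Minimum majority-sign share across replicates (default 3/4).
    amplitude_quantiles:
        Lower/upper pooled quantile cutoffs (default quartiles).
    coherence_min_treatments:
        Minimum number of informative treatments for the coherence check;
        consistency across fewer than 2 observations is vacuous.
    require_both_amplitude:
        Both the receptor and the cytokine effect must pass amplitude
        (exposed because the alternative either-passes reading is not
        excluded by the Methods wording).
    coherence_requires_amplitude:
        Informative treatments for coherence are those where both effects
        pass reproducibility AND amplitude (default); if False,
        reproducibility alone makes a treatment informative.
    """

    reproducibility_fraction: float = 0.75
    amplitude_quantiles: tuple[float, float] = (0.25, 0.75)
    coherence_min_treatments: int = 2
    require_both_amplitude: bool = True
    coherence_requires_amplitude: bool = True

    def __post_init__(self) -> None:
        low, high = self.amplitude_quantiles
        if not (0.0 < low < high < 1.0):
            raise ValueError("amplitude quantiles must satisfy 0 < low < high < 1")
        if not (0.5 < self.reproducibility_fraction <= 1.0):
            raise ValueError("reproducibility_fraction must lie in (0.5, 1]")
        if self.coherence_min_treatments < 1:
            raise ValueError("coherence_min_treatments must be >= 1")


def enumerate_candidate_links(
    receptors: Sequence[str], cytokines: Sequence[str], treatments: Sequence[str]
) -> list[CandidateLink]:
    """Full Cartesian product, in (treatment, receptor, cytokine) order."""
    if not receptors or not cytokines or not treatments:
        raise ValueError("receptor, cytokine and treatment rosters must be non-empty")
    return [
        CandidateLink(t, r, c)
        for t, r, c in itertools.product(treatments, receptors, cytokines)
    ]


def is_reproducible(
    per_replicate_effects: Sequence[float], config: InferenceConfig | None = None
) -> tuple[bool, int]:
    """Majority-sign reproducibility across replicates.

    True iff the majority sign's share is at least the configured fraction;
    returns the majority sign (0 when undefined: a tie or all zeros).
    """
    config = config or InferenceConfig()
    values = np.asarray(per_replicate_effects, dtype=float)
    if values.size < 2:
        raise ValueError("reproducibility needs at least 2 replicate values")
    sign, share = rd.majority_sign(values)
    if sign == 0:
        return False, 0
    return share >= config.reproducibility_fraction, sign


def amplitude_cutoffs(
    pooled_effects: Sequence[float], config: InferenceConfig | None = None
) -> tuple[float, float]:
    """Lower/upper quantile cutoffs of the pooled mean-effect distribution.

    Quantiles are computed by linear interpolation on the sorted values.
    """
    config = config or InferenceConfig()
    pooled = np.asarray(pooled_effects, dtype=float)
    if pooled.size < 4:
        raise ValueError("the pooled amplitude reference needs at least 4 values")
    low, high = config.amplitude_quantiles
    return float(np.quantile(pooled, low)), float(np.quantile(pooled, high))


def passes_amplitude(
    effect: float,
    pooled_effects: Sequence[float],
    config: InferenceConfig | None = None,
) -> bool:
    """True iff ``effect`` reaches the upper or lower pooled quantile cutoff.

    Ties at a cutoff are inclusive.
    """
    lower, upper = amplitude_cutoffs(pooled_effects, config)
    return bool(effect >= upper or effect <= lower)


def is_coherent(
    receptor_profile: Mapping[str, int],
    cytokine_profile: Mapping[str, int],
    config: InferenceConfig | None = None,
) -> tuple[bool, int]:
    """Constant-sign-product check over informative treatments.

    The profiles map treatment -> effect sign (non-zero) for treatments
    where the respective effect is informative; only treatments present in
    both profiles enter the check.  Returns (flag, coherence sign).
    """
    config = config or InferenceConfig()
    common = sorted(set(receptor_profile) & set(cytokine_profile))
    products = {receptor_profile[t] * cytokine_profile[t] for t in common}
    if len(common) < config.coherence_min_treatments or len(products) != 1:
        return False, 0
    return True, products.pop()


class LinkInferrer(BaseEstimator):
    """Three-criteria link retention as an estimator.

    Parameters mirror :class:`InferenceConfig`.  After
    ``fit(receptor_table, cytokine_table)``:

    links_:
        Sorted list of :class:`RetainedLink`.
    candidates_:
        The full candidate list for the shared design.
    summaries_:
        Dict kind -> per-cell summary frame with criterion columns.
    cutoffs_:
        Dict kind -> (lower, upper) pooled amplitude cutoffs.
    """

    def __init__(
        self,
        reproducibility_fraction: float = 0.75,
        amplitude_quantiles: tuple[float, float] = (0.25, 0.75),
        coherence_min_treatments: int = 2,
        require_both_amplitude: bool = True,
        coherence_requires_amplitude: bool = True,
    ):
        self.reproducibility_fraction = reproducibility_fraction
        self.amplitude_quantiles = amplitude_quantiles
        self.coherence_min_treatments = coherence_min_treatments
        self.require_both_amplitude = require_both_amplitude
        self.coherence_requires_amplitude = coherence_requires_amplitude

    def _config(self) -> InferenceConfig:
        return InferenceConfig(
            reproducibility_fraction=self.reproducibility_fraction,
            amplitude_quantiles=tuple(self.amplitude_quantiles),
            coherence_min_treatments=self.coherence_min_treatments,
            require_both_amplitude=self.require_both_amplitude,
            coherence_requires_amplitude=self.coherence_requires_amplitude,
        )

    def fit(self, receptor_table: rd.ResponseTable, cytokine_table: rd.ResponseTable):
        config = self._config()
        if receptor_table.kind != rd.RECEPTOR or cytokine_table.kind != rd.CYTOKINE:
            raise ValueError("fit expects (receptor table, cytokine table) in that order")
        treatments = sorted(set(receptor_table.treatments) & set(cytokine_table.treatments))
        if not treatments:
            raise ValueError("the two tables share no treatments")

        summaries: dict[str, pd.DataFrame] = {}
        cutoffs: dict[str, tuple[float, float]] = {}
        for table in (receptor_table, cytokine_table):
            summary = rd.summarize_effects(table)
            summary = summary.loc[summary.index.get_level_values("treatment").isin(treatments)]
            repro = []
            for (treatment, readout) in summary.index:
                values = table.to_log2().values_for(treatment, readout)
                flag, sign = is_reproducible(values, config)
                repro.append((flag, sign))
            summary["reproducible"] = [f for f, _ in repro]
            summary["sign"] = [s for _, s in repro]
            lower, upper = amplitude_cutoffs(summary["mean_log2"].to_numpy(), config)
            summary["amplitude"] = (summary["mean_log2"] >= upper) | (
                summary["mean_log2"] <= lower
            )
            informative = summary["reproducible"]
            if config.coherence_requires_amplitude:
                informative = informative & summary["amplitude"]
            summary["informative"] = informative
            summaries[table.kind] = summary
            cutoffs[table.kind] = (lower, upper)

        receptors = sorted({r for _, r in summaries[rd.RECEPTOR].index})
        cytokines = sorted({c for _, c in summaries[rd.CYTOKINE].index})
        self.candidates_ = enumerate_candidate_links(receptors, cytokines, treatments)
        self.summaries_ = summaries
        self.cutoffs_ = cutoffs

        def informative_profile(kind: str, readout: str) -> dict[str, int]:
            summary = summaries[kind]
            cells = summary.loc[summary.index.get_level_values(1) == readout]
            return {
                t: int(row["sign"])
                for (t, _), row in cells.iterrows()
                if bool(row["informative"])
            }

        coherence: dict[tuple[str, str], tuple[bool, int]] = {}
        for receptor in receptors:
            rec_profile = informative_profile(rd.RECEPTOR, receptor)
            for cytokine in cytokines:
                cyt_profile = informative_profile(rd.CYTOKINE, cytokine)
                coherence[(receptor, cytokine)] = is_coherent(rec_profile, cyt_profile, config)

        links: list[RetainedLink] = []
        rec_summary = summaries[rd.RECEPTOR]
        cyt_summary = summaries[rd.CYTOKINE]
        for cand in self.candidates_:
            try:
                rec = rec_summary.loc[(cand.treatment, cand.receptor)]
                cyt = cyt_summary.loc[(cand.treatment, cand.cytokine)]
            except KeyError:
                continue
            if not (bool(rec["reproducible"]) and bool(cyt["reproducible"])):
                continue
            if config.require_both_amplitude:
                if not (bool(rec["amplitude"]) and bool(cyt["amplitude"])):
                    continue
            elif not (bool(rec["amplitude"]) or bool(cyt["amplitude"])):
                continue
            coherent, coh_sign = coherence[(cand.receptor, cand.cytokine)]
            if not coherent:
                continue
            links.append(
                RetainedLink(
                    treatment=cand.treatment,
                    receptor=cand.receptor,
                    receptor_sign=int(rec["sign"]),
                    cytokine=cand.cytokine,
                    cytokine_sign=int(cyt["sign"]),
                    coherence_sign=coh_sign,
                )
            )
        self.links_ = sorted(links)
        return self


def infer_links(
    receptor_table: rd.ResponseTable,
    cytokine_table: rd.ResponseTable,
    config: InferenceConfig | None = None,
) -> list[RetainedLink]:
    """Functional wrapper around :class:`LinkInferrer`."""
    config = config or InferenceConfig()
    inferrer = LinkInferrer(
        reproducibility_fraction=config.reproducibility_fraction,
        amplitude_quantiles=config.amplitude_quantiles,
        coherence_min_treatments=config.coherence_min_treatments,
        require_both_amplitude=config.require_both_amplitude,
        coherence_requires_amplitude=config.coherence_requires_amplitude,
    )
    inferrer.fit(receptor_table, cytokine_table)
    return inferrer.links_


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------


def _treatment_node_name(treatment: rd.Treatment) -> str:
    if not treatment.is_combined:
        return next(iter(treatment.components))
    return "_AND_".join(sorted(treatment.components))


def links_to_network(
    links: Sequence[RetainedLink],
    extra_readouts: Sequence[tuple[str, str]] = (),
) -> BooleanNetwork:
    """Assemble retained links into a Boolean network.

    One input node per ligand (self-identity: a free boundary condition),
    one AND node per combined treatment, and for every readout an update
    function ``OR(activating treatments) & !OR(inhibiting treatments)``.
    ``extra_readouts`` may list (name, kind) readouts with no retained
    incoming link; they become free nodes and are logged.

    This OR-of-activators template is a convention; a curated equation file
    can always be loaded directly instead.
    """
    if not links:
        raise ValueError("cannot build a network from an empty link set")
    ligands: list[str] = []
    and_nodes: dict[str, frozenset[str]] = {}
    incoming: dict[str, dict[int, list[str]]] = {}

    def note_target(target: str, sign: int, source: str) -> None:
        slot = incoming.setdefault(target, {1: [], -1: []})
        if source not in slot[sign]:
            slot[sign].append(source)

    for link in links:
        treatment = rd.Treatment(link.treatment)
        for ligand in sorted(treatment.components):
            if ligand not in ligands:
                ligands.append(ligand)
        node = _treatment_node_name(treatment)
        if treatment.is_combined:
            and_nodes[node] = treatment.components
        note_target(link.receptor, link.receptor_sign, node)
        note_target(link.cytokine, link.cytokine_sign, node)

    functions: dict[str, tuple] = {}
    order: list[str] = []
    for ligand in sorted(ligands):
        functions[ligand] = ("var", ligand)
        order.append(ligand)
    for name in sorted(and_nodes):
        expr: tuple | None = None
        for component in sorted(and_nodes[name]):
            expr = ("var", component) if expr is None else ("and", expr, ("var", component))
        functions[name] = expr
        order.append(name)

    def or_expr(sources: Sequence[str]) -> tuple | None:
        expr: tuple | None = None
        for source in sources:
            expr = ("var", source) if expr is None else ("or", expr, ("var", source))
        return expr

    for target in sorted(incoming):
        if target in functions:
            raise ValueError(f"readout {target!r} collides with a ligand/treatment node")
        activators = or_expr(incoming[target][1])
        inhibitors = or_expr(incoming[target][-1])
        if activators is None and inhibitors is None:
            continue
        if activators is None:
            functions[target] = ("not", inhibitors)
        elif inhibitors is None:
            functions[target] = activators
        else:
            functions[target] = ("and", activators, ("not", inhibitors))
        order.append(target)

    for name, kind in extra_readouts:
        if name not in functions:
            logger.info("readout %r has no incoming links; kept as a free node", name)
            functions[name] = ("var", name)
            order.append(name)

    return BooleanNetwork(tuple(order), functions, metadata={"source": "links_to_network"})


def write_links(links: Sequence[RetainedLink], path) -> None:
    """Export links in the six-column TSV layout."""
    frame = pd.DataFrame(
        [
            {
                "treatment": l.treatment,
                "receptor": l.receptor,
                "receptor_sign": l.receptor_sign,
                "cytokine": l.cytokine,
                "cytokine_sign": l.cytokine_sign,
                "coherence_sign": l.coherence_sign,
            }
            for l in links
        ]
    )
    frame.to_csv(path, sep="\t", index=False)
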