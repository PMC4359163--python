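"""Synthetic generators for every pipeline input.

Three forward models make the whole chain testable without any download:

* replicate-structured response tables with *planted* signed
  treatment/receptor/cytokine links plus log2-scale Gaussian noise
  (emulating the structure of supplementary effect tables);
* bulk-secretion mixtures built from known per-population contributions
  and Dirichlet-sampled population fractions (the forward model of
  ``Ca*Na + Cb*Nb + Cc*Nc = K``);
* random Boolean networks with random truth tables, and a curated
  paper-like reconstruction of the monocyte (ivdTEM) regulatory network
  encoding only the qualitative behaviors reported for it.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import response as rd
from .boolnet import BooleanNetwork, parse_network
from .links import RetainedLink
from .mis import (
    CATEGORY_INFLAMMATORY,
    CATEGORY_RTK,
    CATEGORY_TIE2_LIGAND,
    CATEGORY_VEGFR1_LIGAND,
    KNOCK_DOWN,
    OVER_EXPRESS,
    MISQuery,
)

__all__ = [
    "PlantedDesign",
    "MixtureDesign",
    "default_planted_design",
    "generate_response_dataset",
    "generate_mixture_dataset",
    "generate_random_network",
    "paperlike_network",
    "tem_phenotype_queries",
    "PAPERLIKE_DISPLAY_NAMES",
    "PAPERLIKE_CATEGORIES",
]

# Default study-shaped rosters: 7 receptors, 11 cytokines, 12 treatments
# over 6 ligands (four angiogenic ligands alone or combined with one of two
# inflammatory ligands).
_DEFAULT_RECEPTORS = tuple(f"R{i}" for i in range(1, 8))
_DEFAULT_CYTOKINES = tuple(f"C{i}" for i in range(1, 12))
_DEFAULT_TREATMENTS = (
    "L1",
    "L2",
    "L3",
    "L4",
    "L5",
    "L6",
    "L1+L5",
    "L2+L5",
    "L3+L5",
    "L1+L6",
    "L2+L6",
    "L3+L6",
)


@dataclass(frozen=True)
class PlantedDesign:
    """Design of a synthetic response dataset with known ground truth.

    ``planted_links`` holds (treatment, receptor, receptor_sign, cytokine,
    cytokine_sign) tuples; every cell a link touches receives an effect of
    ``sign * effect_size`` log2 units, all remaining cells are pure noise.
    A cell shared by several links must carry one consistent sign.
    """

    receptors: tuple[str, ...] = _DEFAULT_RECEPTORS
    cytokines: tuple[str, ...] = _DEFAULT_CYTOKINES
    treatments: tuple[str, ...] = _DEFAULT_TREATMENTS
    planted_links: tuple[tuple[str, str, int, str, int], ...] = ()
    effect_size: float = 1.0
    noise_sd: float = 0.1
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if self.n_replicates < 3:
            raise ValueError("the replicate design needs at least 3 replicates")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for t, r, sr, c, sc in self.planted_links:
            if t not in self.treatments or r not in self.receptors or c not in self.cytokines:
                raise ValueError(f"planted link ({t}, {r}, {c}) references non-roster members")
            if sr not in (-1, 1) or sc not in (-1, 1):
                raise ValueError("planted signs must be +/-1")

    def truth(self) -> list[RetainedLink]:
        """Ground-truth links as :class:`RetainedLink` objects."""
        return sorted(
            RetainedLink(t, r, sr, c, sc, sr * sc) for t, r, sr, c, sc in self.planted_links
        )


def default_planted_design(
    effect_size: float = 1.0, noise_sd: float = 0.1, n_replicates: int = 4, seed: int = 0
) -> PlantedDesign:
    """The default planted design: strong, broad treatment responses.

    Mirroring the broad remodelling seen in the study system's response
    heatmaps, exactly a quarter of the (treatment, readout) cells per
    readout kind respond upward and a quarter downward (receptors: 21 + 21
    of 84 cells; cytokines: 33 + 33 of 132), so the pooled-quartile
    amplitude cutoffs separate responding cells from noise-only cells.
    Treatments in the first half of the roster drive responding cells up,
    the second half drives them down; one cytokine responds with inverted
    polarity, giving anti-correlated (coherence -1) links.  A link is
    planted for every treatment under which both a receptor cell and a
    cytokine cell respond.
    """
    receptors = _DEFAULT_RECEPTORS
    cytokines = _DEFAULT_CYTOKINES
    treatments = _DEFAULT_TREATMENTS
    partial = {treatments[i] for i in (0, 1, 2, 6, 7, 8)}

    def base_sign(treatment: str) -> int:
        return 1 if treatments.index(treatment) < 6 else -1

    receptor_cells: dict[tuple[str, str], int] = {}
    for r in receptors[:3]:
        for t in treatments:
            receptor_cells[(t, r)] = base_sign(t)
    for t in partial:
        receptor_cells[(t, receptors[3])] = base_sign(t)

    cytokine_cells: dict[tuple[str, str], int] = {}
    for i, c in enumerate(cytokines[:5]):
        flip = -1 if i == 4 else 1  # one anti-correlated cytokine
        for t in treatments:
            cytokine_cells[(t, c)] = flip * base_sign(t)
    for t in partial:
        cytokine_cells[(t, cytokines[5])] = base_sign(t)

    links = []
    for t in treatments:
        planted_r = sorted(r for (tt, r) in receptor_cells if tt == t)
        planted_c = sorted(c for (tt, c) in cytokine_cells if tt == t)
        for r in planted_r:
            for c in planted_c:
                links.append((t, r, receptor_cells[(t, r)], c, cytokine_cells[(t, c)]))
    return PlantedDesign(
        receptors=receptors,
        cytokines=cytokines,
        treatments=treatments,
        planted_links=tuple(links),
        effect_size=effect_size,
        noise_sd=noise_sd,
        n_replicates=n_replicates,
        seed=seed,
    )


def generate_response_dataset(
    design: PlantedDesign,
) -> tuple[rd.ResponseTable, rd.ResponseTable, list[RetainedLink]]:
    """Forward-simulate percent-scale response tables from a planted design.

    Planted cells get per-replicate log2 effects ``sign * effect_size +
    N(0, noise_sd)``, all other cells ``N(0, noise_sd)``; values are
    emitted on the percent scale via ``100 * 2**effect``.
    """
    rng = np.random.default_rng(design.seed)
    effects: dict[str, dict[tuple[str, str], int]] = {rd.RECEPTOR: {}, rd.CYTOKINE: {}}
    for t, r, sr, c, sc in design.planted_links:
        for kind, readout, sign in ((rd.RECEPTOR, r, sr), (rd.CYTOKINE, c, sc)):
            cell = (t, readout)
            prev = effects[kind].get(cell)
            if prev is not None and prev != sign:
                raise ValueError(f"conflicting planted signs for cell {cell}")
            effects[kind][cell] = sign

    tables = {}
    for kind, readouts in ((rd.RECEPTOR, design.receptors), (rd.CYTOKINE, design.cytokines)):
        records = []
        for t in design.treatments:
            for readout in readouts:
                planted = effects[kind].get((t, readout), 0)
                mean = planted * design.effect_size
                for rep in range(1, design.n_replicates + 1):
                    log2_value = mean + (
                        rng.normal(0.0, design.noise_sd) if design.noise_sd > 0 else 0.0
                    )
                    records.append(
                        {
                            "replicate": f"rep{rep}",
                            "treatment": t,
                            "readout": readout,
                            "value": 100.0 * float(np.exp2(log2_value)),
                        }
                    )
        tables[kind] = rd.ResponseTable(pd.DataFrame.from_records(records), kind)
    return tables[rd.RECEPTOR], tables[rd.CYTOKINE], design.truth()


# ---------------------------------------------------------------------------
# Mixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MixtureDesign:
    """Forward model of bulk secretions from three populations.

    Defaults: the DP population (the in-vitro-differentiated TEM) is the
    dominant secretor and DN the weakest (20/60/160 percent of untreated);
    population fractions vary strongly between biological replicates
    (donor-to-donor variability), modelled as Dirichlet(1, 1, 1), i.e.
    uniform over the simplex; measurement noise is Gaussian on the percent
    scale with sd 5.
    """

    true_contributions: tuple[float, float, float] = (20.0, 60.0, 160.0)
    composition_concentration: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd: float = 5.0
    n_replicates: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.true_contributions):
            raise ValueError("true contributions must be non-negative")
        if any(a <= 0 for a in self.composition_concentration):
            raise ValueError("Dirichlet concentrations must be positive")
        if self.n_replicates < 3:
            raise ValueError("need at least 3 replicates")


def generate_mixture_dataset(
    design: MixtureDesign,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample (bulk measurements K, compositions, true contributions).

    Per replicate: composition ~ Dirichlet(concentration), then
    ``K = composition . C + N(0, noise_sd)``, floored at 0 (a percent
    measurement cannot be negative).
    """
    rng = np.random.default_rng(design.seed)
    compositions = rng.dirichlet(design.composition_concentration, size=design.n_replicates)
    truth = np.asarray(design.true_contributions, dtype=float)
    noise = (
        rng.normal(0.0, design.noise_sd, size=design.n_replicates)
        if design.noise_sd > 0
        else np.zeros(design.n_replicates)
    )
    measurements = np.maximum(compositions @ truth + noise, 0.0)
    return measurements, compositions, truth


# ---------------------------------------------------------------------------
# Random Boolean networks
# ---------------------------------------------------------------------------


def _dnf_from_truth_table(regulators: Sequence[str], bits: Sequence[int]) -> tuple:
    """Sum-of-products AST for a truth table over ``regulators``."""
    rows = [
        assignment
        for assignment, bit in zip(itertools.product((0, 1), repeat=len(regulators)), bits)
        if bit
    ]
    if not rows:
        return ("const", 0)
    if len(rows) == len(bits):
        return ("const", 1)
    terms: list[tuple] = []
    for assignment in rows:
        term: tuple | None = None
        for reg, value in zip(regulators, assignment):
            literal = ("var", reg) if value else ("not", ("var", reg))
            term = literal if term is None else ("and", term, literal)
        terms.append(term)
    expr = terms[0]
    for term in terms[1:]:
        expr = ("or", expr, term)
    return expr


def generate_random_network(
    n_nodes: int,
    max_indegree: int = 3,
    seed: int = 0,
    input_fraction: float = 0.25,
) -> BooleanNetwork:
    """A random Boolean network with random truth tables.

    A ``input_fraction`` share of nodes (at least one) become inputs with
    self-identity functions; every other node draws 1..max_indegree
    distinct regulators (possibly including itself) and a uniformly random
    truth table.  Deterministic under ``seed``.
    """
    if not (1 <= n_nodes <= 20):
        raise ValueError("n_nodes must be in 1..20")
    if not (1 <= max_indegree <= 4):
        raise ValueError("max_indegree must be in 1..4")
    rng = np.random.default_rng(seed)
    nodes = tuple(f"N{i}" for i in range(1, n_nodes + 1))
    n_inputs = max(1, int(round(input_fraction * n_nodes)))
    input_nodes = set(rng.choice(n_nodes, size=n_inputs, replace=False).tolist())
    functions: dict[str, tuple] = {}
    for index, node in enumerate(nodes):
        if index in input_nodes:
            functions[node] = ("var", node)
            continue
        k = int(rng.integers(1, max_indegree + 1))
        regulators = [nodes[j] for j in sorted(rng.choice(n_nodes, size=k, replace=False).tolist())]
        bits = rng.integers(0, 2, size=2**k).tolist()
        functions[node] = _dnf_from_truth_table(regulators, bits)
    return BooleanNetwork(nodes, functions, metadata={"seed": seed})


# ---------------------------------------------------------------------------
# Paper-like fixture network (curated reconstruction)
# ---------------------------------------------------------------------------

PAPERLIKE_DISPLAY_NAMES = {
    "VEGF": "VEGF",
    "PLGF": "PlGF",
    "ANG1": "ANG-1",
    "ANG2": "ANG-2",
    "TGFB": "TGF-β",
    "TNFA": "TNF-α",
    "TIE2": "TIE-2",
    "VEGFR1": "VEGFR-1",
    "TGFBR1": "TGFBR-1",
    "TNFR1": "TNF-R1",
    "CCR5": "CCR5",
    "CD11B": "CD11b",
    "CD14": "CD14",
}

PAPERLIKE_LIGANDS = ("VEGF", "PLGF", "ANG1", "ANG2", "TGFB", "TNFA")
PAPERLIKE_RECEPTORS = ("TIE2", "VEGFR1", "TGFBR1", "TNFR1", "CCR5", "CD11B", "CD14")

PAPERLIKE_CATEGORIES = {
    "TIE2": CATEGORY_RTK,
    "VEGFR1": CATEGORY_RTK,
    "TGFB": CATEGORY_INFLAMMATORY,
    "TNFA": CATEGORY_INFLAMMATORY,
    "VEGF": CATEGORY_VEGFR1_LIGAND,
    "PLGF": CATEGORY_VEGFR1_LIGAND,
    "ANG1": CATEGORY_TIE2_LIGAND,
    "ANG2": CATEGORY_TIE2_LIGAND,
}

_PAPERLIKE_EQUATIONS = """\
targets, factors
# ligand inputs: presence/absence is a free boundary condition
VEGF, VEGF
PLGF, PLGF
ANG1, ANG1
ANG2, ANG2
TGFB, TGFB
TNFA, TNFA
# combined treatments (AND nodes)
TNFA_AND_PLGF, TNFA & PLGF
TNFA_AND_ANG2, TNFA & ANG2
TNFA_AND_PLGF_AND_ANG2, TNFA & PLGF & ANG2
# receptors
TIE2, TGFB | TNFA_AND_PLGF | TNFA_AND_ANG2
VEGFR1, (TIE2 & TNFA_AND_PLGF_AND_ANG2) | (!TGFB & VEGF)
CD11B, !TGFB
CD14, TNFA | !TGFB
TGFBR1, 1
TNFR1, 1
CCR5, 1
"""


def paperlike_network() -> BooleanNetwork:
    """A curated, qualitative reconstruction of the monocyte network.

    This is a synthetic stand-in, NOT the study's deposited equation set:
    it is wired only from qualitatively reported behaviors — TGF-β raises
    TIE-2 and lowers VEGFR-1 and CD11b; TNF-α with PlGF or ANG-2 raises
    TIE-2; only the full TNF-α/PlGF/ANG-2 combination (synergising with
    TIE-2 signalling) induces VEGFR-1 — so that the headline clamping
    behaviors hold: forcing TNF-α, ANG-2 and PlGF on yields TIE-2 = 1 and
    VEGFR-1 = 1 in every fixed point, and a TIE-2 knock-down combined with
    TGF-β and VEGF yields VEGFR-1 = 0 in every fixed point.  Metadata
    flags it as a reconstruction.
    """
    network = parse_network(_PAPERLIKE_EQUATIONS)
    return BooleanNetwork(
        network.nodes,
        dict(network.functions),
        metadata={
            "reconstruction": True,
            "display_names": dict(PAPERLIKE_DISPLAY_NAMES),
            "ligands": PAPERLIKE_LIGANDS,
            "receptors": PAPERLIKE_RECEPTORS,
        },
    )


def tem_phenotype_queries(network: BooleanNetwork, k_max: int = 3) -> dict[str, MISQuery]:
    """The two phenotype-transition MIS queries for a TEM-style network.

    Roots are TIE-2 and VEGFR-1: both high defines the highly
    pro-angiogenic (tumor-TEM-like) phenotype, both low the weakly
    pro-angiogenic (blood-TEM-like) one.  Candidate interventions are the
    therapeutically accessible ones: ligands can be added (over-expressed)
    and receptor kinases inhibited (knocked down).
    """
    ligands = [n for n in PAPERLIKE_LIGANDS if n in network.nodes]
    receptors = [n for n in PAPERLIKE_RECEPTORS if n in network.nodes]
    allowed = {n: (OVER_EXPRESS,) for n in ligands}
    allowed.update({n: (KNOCK_DOWN,) for n in receptors})
    candidates = tuple(ligands + receptors)
    return {
        "promoting": MISQuery(
            network=network,
            constraint={"TIE2": 1, "VEGFR1": 1},
            k_max=k_max,
            candidate_nodes=candidates,
            allowed_polarities=allowed,
        ),
        "dampening": MISQuery(
            network=network,
            constraint={"TIE2": 0, "VEGFR1": 0},
            k_max=k_max,
            candidate_nodes=candidates,
            allowed_polarities=allowed,
        ),
    }
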