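# temnet

Boolean-network modelling of pro-angiogenic monocyte plasticity: from
perturbation-response tables to minimal therapeutic intervention sets.

TIE-2-expressing monocytes (TEM) support tumor vascularization; in breast
cancer, tumor-infiltrated TEM are strongly pro-angiogenic while blood TEM
are weakly so, and the two behaviors correspond to TIE-2 and VEGFR-1 being
jointly high or jointly low. `temnet` implements the computational chain
that turns in-vitro treatment-response measurements of such cells into a
predictive Boolean regulatory model and asks which minimal combinations of
treatments flip the cell between those phenotypes. It is aimed at systems
biologists working with cue/signal/response data on small signalling
networks.

## What it computes

**Secretion deconvolution.** Cultures mix three populations (DN, SP and
DP cells, the last being the in-vitro-differentiated TEM). For each
cytokine and treatment, every biological replicate *i* gives one equation

    Ca·Na_i + Cb·Nb_i + Cc·Nc_i = K_i

with N the measured population fractions and K the bulk
percent-of-untreated secretion change. All C(n,3) replicate triples (4
systems at n = 4, 84 at n = 9) are solved exactly; the per-population
contributions Ca, Cb, Cc are the medians across non-singular triples, and
values below the 1% floor are clamped to it.

**Link inference.** A candidate link is a (treatment, receptor, cytokine)
triple — 924 of them for the 7-receptor x 11-cytokine x 12-treatment
design. A link is retained iff, on the log2(percent/100) scale,

1. *reproducibility*: >= 3/4 of replicates agree on the effect direction,
   for both readouts;
2. *amplitude*: both mean effects reach the upper or lower quartile of the
   pooled per-cell mean effects of their readout kind;
3. *coherence*: across informative treatments the receptor-cytokine sign
   product is constant (always correlated, or always anti-correlated).

**Boolean dynamics and intervention sets.** Retained links assemble into
a Boolean network (ligand inputs, AND nodes for combined treatments,
OR-of-activators AND NOT-OR-of-inhibitors update functions), or a curated
equation file in the BoolNet-style `targets, factors` dialect is loaded
directly. Phenotypes are fixed points; treatments are clamps (ligand
addition = clamp 1, kinase inhibitor = clamp 0). A Minimal Intervention
Set (MIS) is a smallest clamp set (here <= 3) such that the clamped
network has a fixed point and every fixed point satisfies the phenotype
constraint — e.g. TIE-2 = VEGFR-1 = 1. Two solvers are provided: a
brute-force oracle and a tree-unrolling solver that propagates required
polarities from the constraint (root) nodes backwards along regulator
paths; their outputs are verified set-equal on random-network batteries.

A synthetic-data module generates every input with known ground truth
(planted links, known population contributions, random networks, and a
curated qualitative reconstruction of the TEM network), so the full chain
runs and is tested without any external data.

## Worked example

Library use — ask the curated fixture network which minimal treatments
force the highly pro-angiogenic phenotype:

```python
>>> import temnet as tn
>>> network = tn.paperlike_network()
>>> queries = tn.tem_phenotype_queries(network)   # roots: TIE2, VEGFR1
>>> [str(s) for s in tn.mis_unroll(queries["promoting"])]
['{ANG2^, PLGF^, TNFA^}']
>>> [str(s) for s in tn.mis_unroll(queries["dampening"])]
['{TGFB^, TIE2v}', '{TIE2v, VEGFR1v}']
```

The single promoting MIS is the TNF-α/PlGF/ANG-2 triple (`^` = clamp on);
no pair or single treatment suffices. Dampening requires inhibiting TIE-2
(`v` = clamp off) together with either TGF-β addition or VEGFR-1
inhibition.

Command line — run the whole pipeline on synthetic inputs:

```
$ temnet run --out-dir demo --seed 1
# temnet run summary

Seed: 1

Retained 234 of 924 candidate links.
Deconvolution solved 84 replicate-triple systems.
Fixed points: 64 on the 14-node core (roots: C1, C2).

## Minimal intervention sets

0 promoting and 7 dampening set(s) of size <= 3.
...
```

The 234 retained links are exactly the planted ones (the generator's
ground truth is written alongside by `temnet make-fixtures`); 84 is
C(9,3), the number of replicate-triple systems solved for the 9-replicate
mixture; the MIS table lists, per intervention set, the inhibited
receptors and up-regulated ligands. Artifacts (`retained_links.tsv`,
`network.bnet`, `fixed_points.tsv`, `mis.json`, `manifest.json`, ...) are
byte-identical across reruns with the same seed.

Other subcommands: `make-fixtures`, `deconvolve`, `infer-links`,
`build-network`, `fixed-points`, `mis`, `report`.

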