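"""Synthetic benchmark generators with planted, recoverable structure.

Real CRISPR screens are large downloads; these generators emulate their
statistical shape at desk scale so every component of the package can be
exercised and validated end-to-end:

* :func:`gen_offtarget` — sgRNA–DNA aligned pairs whose activity decays
  exponentially with position-weighted mismatch penalties (mismatch counts
  uniform on 0..6, mirroring the <=6-mismatch negative mining used for real
  off-target sets), scaled to indel-frequency percent and labelled by the
  top-activity fraction.
* :func:`gen_ontarget` — guide efficiencies driven by planted per-position
  dimer effects plus a gene-level effect transmitted through a random
  gene–gene interaction network (so the NetExpress feature is genuinely
  informative), with per-cell-line expression so the same guide scores
  differently in different cell lines.
* :func:`gen_toy_fixtures` — hand-checkable micro-fixtures for exact tests.

Every generator is a pure function of its config's ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .encoding import AlignedPair, CasSystem, GuideRecord
from .errors import ValidationError
from .netexpress import ExpressionProfile, GeneNetwork, compute_all
from .training import label_top_fraction

__all__ = [
    "OffTargetSimConfig",
    "OnTargetSimConfig",
    "OffTargetSim",
    "OnTargetSim",
    "ToyFixtures",
    "gen_offtarget",
    "gen_ontarget",
    "gen_toy_fixtures",
]

_BASES = np.array(list("ACGT"))


def _random_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    idx = rng.integers(0, 4, size=(n, length))
    return ["".join(_BASES[row]) for row in idx]


# ---------------------------------------------------------------------------
# off-target
# ---------------------------------------------------------------------------

@dataclass
class OffTargetSimConfig:
    """Study conditions for the off-target benchmark.

    Defaults give 50 guides x 80 decoys = 4000 pairs of Cas9 length 20.
    ``position_weights`` default to a 5'->3' ramp (0.05 -> 0.5): mismatches
    near the 3' (PAM-proximal, seed) end of the spacer are penalised more,
    matching the known tolerance of 5'-distal mismatches. Activities are
    mapped to indel-frequency percent in [0, 100]; ``noise_sd`` is on that
    scale. ``imbalance_labeling`` is the top-activity fraction labelled
    positive (0.2 default; small values emulate heavy screen imbalance).
    """

    n_guides: int = 50
    decoys_per_guide: int = 80
    pair_length: int = 20
    position_weights: Optional[np.ndarray] = None
    max_mismatches: int = 6
    noise_sd: float = 2.0
    imbalance_labeling: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_guides < 1 or self.decoys_per_guide < 1:
            raise ValidationError("n_guides and decoys_per_guide must be positive")
        if self.position_weights is None:
            p = np.arange(self.pair_length)
            self.position_weights = 0.05 + 0.45 * p / (self.pair_length - 1)
        self.position_weights = np.asarray(self.position_weights, dtype=float)
        if self.position_weights.shape != (self.pair_length,):
            raise ValidationError("position_weights must have length pair_length")
        if (self.position_weights < 0).any():
            raise ValidationError("position_weights must be nonnegative")
        if not 0 < self.imbalance_labeling < 1:
            raise ValidationError("imbalance_labeling must be in (0, 1)")


@dataclass
class OffTargetSim:
    pairs: list[AlignedPair]
    guide_ids: np.ndarray  # guide index per pair, for leave-sgRNAs-out splits
    config: OffTargetSimConfig


def latent_activity(weights: np.ndarray, mismatch_positions: Sequence[int]) -> float:
    """Noise-free activity (percent) of a pair mismatched at the given positions."""
    return 100.0 * float(np.exp(-np.sum(np.asarray(weights)[list(mismatch_positions)])))


def gen_offtarget(cfg: OffTargetSimConfig) -> OffTargetSim:
    rng = np.random.default_rng(cfg.seed)
    length = cfg.pair_length
    system = CasSystem.CAS9 if length == 20 else CasSystem.CAS12A
    guides = _random_seqs(rng, cfg.n_guides, length)
    pairs: list[AlignedPair] = []
    guide_ids = []
    scores = []
    for gi, guide in enumerate(guides):
        for _ in range(cfg.decoys_per_guide):
            m = int(rng.integers(0, cfg.max_mismatches + 1))
            pos = rng.choice(length, size=m, replace=False)
            dna = list(guide)
            for p in pos:
                choices = [b for b in "ACGT" if b != guide[p]]
                dna[p] = choices[int(rng.integers(0, 3))]
            act = latent_activity(cfg.position_weights, pos)
            score = float(np.clip(act + rng.normal(0.0, cfg.noise_sd), 0.0, 100.0))
            pairs.append(
                AlignedPair(sgrna_seq=guide, dna_seq="".join(dna), score=score, system=system)
            )
            guide_ids.append(gi)
            scores.append(score)
    labels = label_top_fraction(scores, cfg.imbalance_labeling)
    for pair, lab in zip(pairs, labels):
        pair.label = int(lab)
    return OffTargetSim(pairs=pairs, guide_ids=np.asarray(guide_ids), config=cfg)


# ---------------------------------------------------------------------------
# on-target
# ---------------------------------------------------------------------------

@dataclass
class OnTargetSimConfig:
    """Study conditions for the on-target benchmark.

    Efficiency of each guide is generated as::

        efficiency = sum_k dimer_effects[k, token_k]
                   + gene_effect_via_network * z(NetExpress(gene, cell line))
                   + Normal(0, noise_sd)

    where z(.) standardises NetExpress across genes within a cell line.
    ``dimer_effects`` is a (L-1, 16) array; when omitted it is drawn
    N(0, 0.3) per (position, dimer), giving a sequence term of s.d. ~1.7
    for 34-base guides — a clearly learnable but non-trivial signal next to
    the unit-scale gene term and ``noise_sd`` 0.5. Two cell lines share the
    network but have independent expression, so the same guide receives
    discordant efficiencies across cell lines.
    """

    n_guides: int = 1000
    seq_length: int = 34
    dimer_effects: Optional[np.ndarray] = None
    dimer_effect_sd: float = 0.3
    gene_effect_via_network: float = 1.0
    n_genes: int = 60
    network_density: float = 0.08
    cell_lines: tuple[str, ...] = ("CL1", "CL2")
    shared_expression: bool = False  # reuse one expression draw for all cell lines
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.seq_length < 2:
            raise ValidationError("seq_length must be >= 2")
        if self.n_genes < 2:
            raise ValidationError("n_genes must be >= 2")
        if not 0 <= self.network_density <= 1:
            raise ValidationError("network_density must be in [0, 1]")
        if self.dimer_effects is not None:
            self.dimer_effects = np.asarray(self.dimer_effects, dtype=float)
            if self.dimer_effects.shape != (self.seq_length - 1, 16):
                raise ValidationError(
                    f"dimer_effects must have shape ({self.seq_length - 1}, 16)"
                )


@dataclass
class OnTargetSim:
    records: list[GuideRecord]
    network: GeneNetwork
    expression: dict[str, ExpressionProfile]
    dimer_effects: np.ndarray
    netexpress: dict[tuple[str, str], float]  # (cell_line, gene) -> raw score
    config: OnTargetSimConfig


def gen_ontarget(cfg: OnTargetSimConfig) -> OnTargetSim:
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]

    # random interaction network, confidences U(0.2, 1)
    er = nx.gnp_random_graph(cfg.n_genes, cfg.network_density, seed=int(rng.integers(2**31)))
    edges = [
        (genes[a], genes[b], float(rng.uniform(0.2, 1.0))) for a, b in er.edges
    ]
    network = GeneNetwork.from_edges(edges)
    for g in genes:
        network.add_node(g)  # keep isolated genes addressable

    expression: dict[str, ExpressionProfile] = {}
    ne_raw: dict[tuple[str, str], float] = {}
    ne_z: dict[tuple[str, str], float] = {}
    shared_vals = (
        dict(zip(genes, rng.lognormal(mean=1.0, sigma=0.75, size=cfg.n_genes)))
        if cfg.shared_expression
        else None
    )
    for cl in cfg.cell_lines:
        vals = shared_vals or dict(
            zip(genes, rng.lognormal(mean=1.0, sigma=0.75, size=cfg.n_genes))
        )
        prof = ExpressionProfile(cell_line=cl, values=vals)
        expression[cl] = prof
        scores = compute_all(network, prof)
        arr = np.array([scores[g].score for g in genes])
        sd = arr.std()
        z = (arr - arr.mean()) / sd if sd > 0 else np.zeros_like(arr)
        for g, raw, zz in zip(genes, arr, z):
            ne_raw[(cl, g)] = float(raw)
            ne_z[(cl, g)] = float(zz)

    effects = cfg.dimer_effects
    if effects is None:
        effects = rng.normal(0.0, cfg.dimer_effect_sd, size=(cfg.seq_length - 1, 16))

    seqs = _random_seqs(rng, cfg.n_guides, cfg.seq_length)
    base_index = {b: i for i, b in enumerate("ACGT")}
    records: list[GuideRecord] = []
    for seq in seqs:
        gene = genes[int(rng.integers(0, cfg.n_genes))]
        idx = np.array([base_index[b] for b in seq])
        toks = 4 * idx[:-1] + idx[1:]
        seq_term = float(effects[np.arange(len(toks)), toks].sum())
        for cl in cfg.cell_lines:
            eff = (
                seq_term
                + cfg.gene_effect_via_network * ne_z[(cl, gene)]
                + float(rng.normal(0.0, cfg.noise_sd))
            )
            records.append(
                GuideRecord(
                    seq=seq,
                    efficiency=eff,
                    gene_id=gene,
                    cell_line=cl,
                    netexpress=ne_raw[(cl, gene)],
                )
            )
    return OnTargetSim(
        records=records,
        network=network,
        expression=expression,
        dimer_effects=effects,
        netexpress=ne_raw,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# toy fixtures
# ---------------------------------------------------------------------------

@dataclass
class ToyFixtures:
    """Hand-computable micro-fixtures for exact regression tests."""

    network: GeneNetwork
    expression: ExpressionProfile
    expected_netexpress: dict[str, float]
    guides: list[GuideRecord]
    perfect_pair: AlignedPair


def gen_toy_fixtures() -> ToyFixtures:
    # 6-node network: path A-B-C (unit weights), D-E (0.5), F isolated
    network = GeneNetwork.from_edges(
        [("A", "B", 1.0), ("B", "C", 1.0), ("D", "E", 0.5)]
    )
    network.add_node("F")
    expression = ExpressionProfile(
        cell_line="TOY", values={g: 1.0 for g in "ABCDE"}
    )
    expected = {"A": 1.0, "B": 2.0, "C": 1.0, "D": 0.5, "E": 0.5, "F": 0.0}
    guides = [
        GuideRecord(seq="AUGCU", efficiency=0.5, gene_id="A", cell_line="TOY"),
        GuideRecord(seq="GGGGG", efficiency=-1.0, gene_id="B", cell_line="TOY"),
        GuideRecord(seq="ACGTA", efficiency=0.0, gene_id="C", cell_line="TOY"),
        GuideRecord(seq="TTTCA", efficiency=1.2, gene_id="D", cell_line="TOY"),
        GuideRecord(seq="CATGC", efficiency=-0.3, gene_id="F", cell_line="TOY"),
    ]
    perfect_pair = AlignedPair(
        sgrna_seq="ACGTACGTACGTACGTACGT",
        dna_seq="ACGTACGTACGTACGTACGT",
        score=95.0,
        system=CasSystem.CAS9,
    )
    return ToyFixtures(
        network=network,
        expression=expression,
        expected_netexpress=expected,
        guides=guides,
        perfect_pair=perfect_pair,
    )
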