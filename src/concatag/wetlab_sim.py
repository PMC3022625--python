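"""Simulation of the concatemer-tag protocol with full truth tracking.

Stages, in protocol order: assemble adaptor-tagged PCR products for every
panel gene, draw a molecule pool from a ground-truth expression profile,
double-digest each product into its canonical tag, ligate tags into
orientation-alternating concatemers via sticky-end joins, size-select
500-1200 bp products, and sequence a fixed number of randomly picked
clones with an optional substitution error model.

Canonical-tag convention: a digested tag is written 5'->3' on the strand
that begins with the BamHI hexamer and ends with the HindIII hexamer,
overhangs filled in.  Junction hexamers inside a concatemer are therefore
shared by both flanking tags; the deconvolution module uses the identical
convention so that parsing is boundary-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .dna import (
    BAMHI_OVERHANG,
    BAMHI_SITE,
    HINDIII_OVERHANG,
    HINDIII_SITE,
    find_all,
    reverse_complement,
)
from .panel_design import GeneTarget, PrimerPanel, UniversalAdaptors

__all__ = [
    "Amplicon",
    "DigestedTag",
    "CloneInsert",
    "SimConfig",
    "CloneRead",
    "SimulationResult",
    "DigestionError",
    "make_amplicons",
    "sample_tag_pool",
    "digest",
    "ligate_concatemers",
    "size_select",
    "sequence_clones",
    "simulate_sample",
]

Orientation = Literal["F", "RC"]


class DigestionError(ValueError):
    """Amplicon does not carry exactly one site per enzyme at the adaptor offsets."""


@dataclass(frozen=True)
class Amplicon:
    gene_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DigestedTag:
    """Double-digested fragment in canonical form (BamHI hexamer first)."""

    gene_id: str
    canonical_sequence: str
    left_end: str = BAMHI_OVERHANG
    right_end: str = HINDIII_OVERHANG

    @property
    def length(self) -> int:
        return len(self.canonical_sequence)

    def oriented(self, orientation: Orientation) -> str:
        if orientation == "F":
            return self.canonical_sequence
        return reverse_complement(self.canonical_sequence)


@dataclass(frozen=True)
class CloneInsert:
    clone_id: str
    tags: tuple[tuple[DigestedTag, Orientation], ...]
    insert_sequence: str

    @property
    def length(self) -> int:
        return len(self.insert_sequence)

    @property
    def terminal_ends(self) -> tuple[str, str]:
        """Overhang compatibility of (left, right) termini."""
        left = "BamHI" if self.tags[0][1] == "F" else "HindIII"
        right = "HindIII" if self.tags[-1][1] == "F" else "BamHI"
        return (left, right)

    @property
    def cloneable(self) -> bool:
        return set(self.terminal_ends) == {"BamHI", "HindIII"}


@dataclass(frozen=True)
class SimConfig:
    n_clones: int = 300
    tag_pool_depth: int = 100_000
    n_ligation_products: int = 2000
    stop_prob: float = 0.08
    seq_error_rate: float = 0.0
    size_window: tuple[int, int] = (500, 1200)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError(f"n_clones must be >= 1, got {self.n_clones}")
        if not (0 <= self.seq_error_rate < 0.1):
            raise ValueError(f"seq_error_rate must be in [0, 0.1), got {self.seq_error_rate}")
        if not (0 < self.stop_prob < 1):
            raise ValueError("stop_prob must be in (0, 1)")
        if self.size_window[0] >= self.size_window[1]:
            raise ValueError("size window min must be below max")


@dataclass(frozen=True)
class CloneRead:
    clone_id: str
    sequence: str
    truth: tuple[tuple[str, Orientation], ...]  # ordered (gene_id, orientation)


@dataclass
class SimulationResult:
    sample_id: str
    reads: list[CloneRead]
    inserts: list[CloneInsert]
    config: SimConfig
    pool_counts: dict[str, int] = field(default_factory=dict)

    def truth_rows(self) -> list[tuple[str, int, str, str]]:
        """(clone_id, position, gene_id, orientation) rows for the truth table."""
        rows = []
        for read in self.reads:
            for i, (gid, ori) in enumerate(read.truth):
                rows.append((read.clone_id, i, gid, ori))
        return rows


# ---------------------------------------------------------------------------
# expression profile
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-sample relative transcript abundances (normalized to sum 1)."""

    sample_id: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("profile has no genes")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("negative abundance weight")
        total = sum(self.weights.values())
        if total <= 0:
            raise ValueError(f"profile {self.sample_id}: all weights are zero")
        object.__setattr__(
            self, "weights", {g: w / total for g, w in self.weights.items()}
        )


# ---------------------------------------------------------------------------
# protocol stages
# ---------------------------------------------------------------------------


def make_amplicons(panel: PrimerPanel, genes: list[GeneTarget]) -> list[Amplicon]:
    """Assemble the full PCR product for every panel pair, in panel order."""
    by_id = {g.gene_id: g for g in genes}
    out = []
    for pair in panel.pairs:
        if pair.gene_id not in by_id:
            raise ValueError(f"panel gene {pair.gene_id} missing from gene set")
        out.append(Amplicon(pair.gene_id, pair.amplicon_sequence(by_id[pair.gene_id])))
    return out


def sample_tag_pool(
    profile: ExpressionProfile,
    amplicons: list[Amplicon],
    depth: int,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Multinomial molecule counts per gene, modelling unbiased RT + PCR."""
    if depth < 1:
        raise ValueError("pool depth must be >= 1")
    gene_ids = [a.gene_id for a in amplicons]
    missing = [g for g in gene_ids if g not in profile.weights]
    if missing:
        raise ValueError(f"profile {profile.sample_id} lacks weights for {missing}")
    w = np.array([profile.weights[g] for g in gene_ids], dtype=float)
    if w.sum() <= 0:
        raise ValueError("all panel genes have zero weight")
    counts = rng.multinomial(depth, w / w.sum())
    return dict(zip(gene_ids, (int(c) for c in counts)))


def digest(amplicon: Amplicon, adaptors: UniversalAdaptors) -> DigestedTag:
    """Cut at G^GATCC and A^AGCTT, returning the canonical middle fragment.

    The canonical sequence retains the full reconstituted hexamer at each
    end (overhangs filled); the discarded outer remnants are the bases 5'
    of each hexamer, i.e. ``adaptors.left_discard``/``right_discard`` bp.
    """
    seq = amplicon.sequence
    bam = find_all(seq, BAMHI_SITE)
    hind = find_all(seq, HINDIII_SITE)
    want_bam = adaptors.bamhi_offset
    want_hind = len(seq) - adaptors.hindiii_offset - 6
    if bam != [want_bam]:
        raise DigestionError(
            f"{amplicon.gene_id}: expected one GGATCC at {want_bam}, found at {bam}"
        )
    if hind != [want_hind]:
        raise DigestionError(
            f"{amplicon.gene_id}: expected one AAGCTT at {want_hind}, found at {hind}"
        )
    canonical = seq[want_bam : want_hind + 6]
    return DigestedTag(gene_id=amplicon.gene_id, canonical_sequence=canonical)


def _chain_insert(tags: list[tuple[DigestedTag, Orientation]]) -> str:
    """Concatenate oriented tags sharing the junction hexamers."""
    parts = [tags[0][0].oriented(tags[0][1])]
    for tag, ori in tags[1:]:
        parts.append(tag.oriented(ori)[6:])
    return "".join(parts)


def ligate_concatemers(
    tag_counts: dict[str, int],
    tags_by_gene: dict[str, DigestedTag],
    rng: np.random.Generator,
    stop_prob: float = 0.08,
    n_products: int = 2000,
) -> list[CloneInsert]:
    """Grow random sticky-end concatemer chains from the tag pool.

    Each chain starts from a random tag in a random orientation and extends
    rightward; a join is only possible between like overhangs, which forces
    strict F/RC alternation.  Chain length is geometric with ``stop_prob``.
    A product is cloneable iff its termini are one BamHI- and one
    HindIII-compatible end (odd tag count under strict alternation).
    """
    gene_ids = [g for g, c in tag_counts.items() if c > 0]
    if not gene_ids:
        raise ValueError("empty tag pool")
    weights = np.array([tag_counts[g] for g in gene_ids], dtype=float)
    weights /= weights.sum()

    # draw chain lengths, then all gene picks in one vectorized call
    lengths = rng.geometric(stop_prob, size=n_products)
    total = int(lengths.sum())
    picks = rng.choice(len(gene_ids), size=total, p=weights)
    first_oris = rng.integers(0, 2, size=n_products)

    inserts: list[CloneInsert] = []
    offset = 0
    for i in range(n_products):
        k = int(lengths[i])
        chain_genes = picks[offset : offset + k]
        offset += k
        ori0: Orientation = "F" if first_oris[i] == 0 else "RC"
        chain: list[tuple[DigestedTag, Orientation]] = []
        ori = ori0
        for gi in chain_genes:
            chain.append((tags_by_gene[gene_ids[gi]], ori))
            ori = "RC" if ori == "F" else "F"
        inserts.append(
            CloneInsert(
                clone_id=f"product_{i:05d}",
                tags=tuple(chain),
                insert_sequence=_chain_insert(chain),
            )
        )
    return inserts


def size_select(
    candidates: list[CloneInsert], window: tuple[int, int] = (500, 1200)
) -> list[CloneInsert]:
    """Keep cloneable inserts whose length lies in the inclusive window."""
    lo, hi = window
    if lo >= hi:
        raise ValueError("size window min must be below max")
    survivors = [c for c in candidates if c.cloneable and lo <= c.length <= hi]
    if not survivors:
        import warnings

        warnings.warn("size selection produced no survivors", stacklevel=2)
    return survivors


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    bases = "ACGT"
    for p in pos:
        alternatives = bases.replace(chars[p], "")
        chars[p] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def sequence_clones(
    inserts: list[CloneInsert],
    n_clones: int,
    seq_error_rate: float,
    rng: np.random.Generator,
) -> list[CloneRead]:
    """Pick ``n_clones`` inserts uniformly with replacement and read them
    end to end with i.i.d. substitution errors."""
    if n_clones <= 0:
        raise ValueError(f"n_clones must be positive, got {n_clones}")
    if not inserts:
        raise ValueError("no inserts survived size selection; nothing to sequence")
    idx = rng.integers(0, len(inserts), size=n_clones)
    reads = []
    for i, j in enumerate(idx):
        ins = inserts[int(j)]
        seq = ins.insert_sequence
        if seq_error_rate > 0:
            seq = _mutate(seq, seq_error_rate, rng)
        reads.append(
            CloneRead(
                clone_id=f"clone_{i:04d}",
                sequence=seq,
                truth=tuple((t.gene_id, o) for t, o in ins.tags),
            )
        )
    return reads


def simulate_sample(
    sample_id: str,
    panel: PrimerPanel,
    genes: list[GeneTarget],
    profile: ExpressionProfile,
    config: SimConfig = SimConfig(),
    rng: np.random.Generator | None = None,
) -> SimulationResult:
    """Run the full protocol for one sample.

    All stochastic stages draw from a single seeded stream in fixed order:
    pool sampling, ligation, clone picking, sequencing errors.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    amplicons = make_amplicons(panel, genes)
    pool = sample_tag_pool(profile, amplicons, config.tag_pool_depth, rng)
    tags_by_gene = {a.gene_id: digest(a, panel.adaptors) for a in amplicons}
    candidates = ligate_concatemers(
        pool, tags_by_gene, rng, stop_prob=config.stop_prob, n_products=config.n_ligation_products
    )
    survivors = size_select(candidates, config.size_window)
    reads = sequence_clones(survivors, config.n_clones, config.seq_error_rate, rng)
    return SimulationResult(
        sample_id=sample_id, reads=reads, inserts=survivors, config=config, pool_counts=pool
    )
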