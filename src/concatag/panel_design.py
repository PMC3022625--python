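"""Design of multiplex chimeric primer panels.

Each primer is chimeric: a 3' gene-specific part (16-20 nt) fused to a 5'
universal adaptor tag carrying a restriction site (BamHI on the forward
adaptor, HindIII on the reverse one).  The full PCR product is therefore

    forward_tag + fwd_specific + internal gene span + rc(rev_specific) + rc(reverse_tag)

and its length must sit in an 85 +/- 7 bp window.  Digestion with both
enzymes trims a fixed outer remnant from each adaptor, so the product
window maps one-to-one onto a digested-tag length window (60-70 bp by
default); both windows are enforced at candidate enumeration time.

Panel selection picks one primer pair per gene so that the melting
temperatures of all gene-specific parts differ pairwise by at most 5 C,
minimising the Tm spread with fully deterministic tie-breaking.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from functools import lru_cache
from statistics import mean, stdev

from Bio.SeqUtils import MeltingTemp as _mt

from .dna import (
    BAMHI_SITE,
    HINDIII_SITE,
    find_all,
    reverse_complement,
    validate_dna,
)

__all__ = [
    "GeneTarget",
    "UniversalAdaptors",
    "TmParameters",
    "DesignConstraints",
    "ChimericPrimerPair",
    "PrimerPanel",
    "PanelValidationReport",
    "NoCandidatesError",
    "PanelInfeasibleError",
    "melting_temperature",
    "enumerate_candidates",
    "design_panel",
    "validate_panel",
    "DEFAULT_ADAPTORS",
    "DEFAULT_CONSTRAINTS",
]


class NoCandidatesError(ValueError):
    """No primer pair satisfies the design constraints for a gene."""


class PanelInfeasibleError(ValueError):
    """No joint primer assignment satisfies the pairwise Tm constraint."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneTarget:
    """A target gene sequence; ``is_control`` marks the internal control."""

    gene_id: str
    sequence: str
    is_control: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", validate_dna(self.sequence, name=f"gene {self.gene_id}")
        )


@dataclass(frozen=True)
class UniversalAdaptors:
    """The shared 18/19 nt adaptor tags used as universal primers.

    ``bamhi_offset``/``hindiii_offset`` are the 0-based positions of the
    recognition hexamer within each tag.  After double digestion the bases
    5' of the BamHI hexamer and 5' of the HindIII hexamer are discarded, so
    each offset equals the number of bases trimmed from that end of the
    PCR product.
    """

    forward_tag: str
    reverse_tag: str

    def __post_init__(self) -> None:
        fwd = validate_dna(self.forward_tag, name="forward adaptor")
        rev = validate_dna(self.reverse_tag, name="reverse adaptor")
        object.__setattr__(self, "forward_tag", fwd)
        object.__setattr__(self, "reverse_tag", rev)
        if len(fwd) != 18:
            raise ValueError(f"forward adaptor must be 18 nt, got {len(fwd)}")
        if len(rev) != 19:
            raise ValueError(f"reverse adaptor must be 19 nt, got {len(rev)}")
        for tag, name, want, avoid in (
            (fwd, "forward adaptor", BAMHI_SITE, HINDIII_SITE),
            (rev, "reverse adaptor", HINDIII_SITE, BAMHI_SITE),
        ):
            hits = find_all(tag, want)
            if len(hits) != 1:
                raise ValueError(f"{name} must contain exactly one {want}, found {len(hits)}")
            if find_all(tag, avoid):
                raise ValueError(f"{name} must not contain {avoid}")

    @property
    def bamhi_offset(self) -> int:
        return self.forward_tag.find(BAMHI_SITE)

    @property
    def hindiii_offset(self) -> int:
        return self.reverse_tag.find(HINDIII_SITE)

    @property
    def left_discard(self) -> int:
        """Bases trimmed from the BamHI end of a product on digestion."""
        return self.bamhi_offset

    @property
    def right_discard(self) -> int:
        """Bases trimmed from the HindIII end of a product on digestion."""
        return self.hindiii_offset

    @property
    def overhead(self) -> int:
        """Total adaptor bases added to the genomic span by the two tags."""
        return len(self.forward_tag) + len(self.reverse_tag)


#: Default adaptors: hexamer at offset 10 in both tags, so digestion trims
#: 10 bp from each end and an 85 bp product yields a 65 bp tag.
DEFAULT_ADAPTORS = UniversalAdaptors(
    forward_tag="ACTGCGTACGGGATCCAT",
    reverse_tag="GCATACGTCGAAGCTTCAG",
)


@dataclass(frozen=True)
class TmParameters:
    """Nearest-neighbor Tm model settings.

    Defaults use the unified SantaLucia 2004 table with the Owczarzy 2008
    divalent-cation correction at the multiplex buffer conditions
    (50 mM KCl, 5 mM MgCl2, 200 nM primer).
    """

    table: str = "santalucia2004"
    primer_nM: float = 200.0
    monovalent_mM: float = 50.0
    divalent_mM: float = 5.0

    def _nn_table(self):
        tables = {"santalucia2004": _mt.DNA_NN3, "santalucia1997": _mt.DNA_NN1}
        try:
            return tables[self.table]
        except KeyError:
            raise ValueError(f"unknown Tm parameter table {self.table!r}") from None


@dataclass(frozen=True)
class DesignConstraints:
    specific_len_range: tuple[int, int] = (16, 20)
    amplicon_center: int = 85
    amplicon_tol: int = 7
    tag_len_range: tuple[int, int] = (60, 70)
    max_pairwise_dtm: float = 5.0
    tm_params: TmParameters = field(default_factory=TmParameters)

    def __post_init__(self) -> None:
        if self.specific_len_range[0] < 1 or self.specific_len_range[0] > self.specific_len_range[1]:
            raise ValueError("invalid specific primer length range")
        if self.amplicon_center <= 0 or self.amplicon_tol < 0 or self.max_pairwise_dtm <= 0:
            raise ValueError("amplicon and Tm bounds must be positive")

    @property
    def amplicon_window(self) -> tuple[int, int]:
        """Inclusive [min, max] allowed full PCR-product length."""
        return (self.amplicon_center - self.amplicon_tol, self.amplicon_center + self.amplicon_tol)


DEFAULT_CONSTRAINTS = DesignConstraints()


@dataclass(frozen=True)
class ChimericPrimerPair:
    """One gene's designed primer pair.

    ``amplicon_interval`` is the 0-based half-open genomic window on the
    gene's forward strand; ``amplicon_len`` is the full PCR-product length
    (genomic span plus the 37 nt of adaptor tags).  Tm values refer to the
    gene-specific parts only.
    """

    gene_id: str
    fwd_specific: str
    rev_specific: str
    amplicon_interval: tuple[int, int]
    amplicon_len: int
    tm_fwd: float
    tm_rev: float
    adaptors: UniversalAdaptors = DEFAULT_ADAPTORS

    @property
    def fwd_full(self) -> str:
        return self.adaptors.forward_tag + self.fwd_specific

    @property
    def rev_full(self) -> str:
        return self.adaptors.reverse_tag + self.rev_specific

    @property
    def tm_low(self) -> float:
        return min(self.tm_fwd, self.tm_rev)

    @property
    def tm_high(self) -> float:
        return max(self.tm_fwd, self.tm_rev)

    def amplicon_sequence(self, gene: GeneTarget) -> str:
        """Assemble the full PCR product on the given gene."""
        if gene.gene_id != self.gene_id:
            raise ValueError(f"primer pair for {self.gene_id} applied to gene {gene.gene_id}")
        start, end = self.amplicon_interval
        span = gene.sequence[start:end]
        if not span.startswith(self.fwd_specific):
            raise ValueError(f"{self.gene_id}: forward primer does not match gene at {start}")
        if not span.endswith(reverse_complement(self.rev_specific)):
            raise ValueError(f"{self.gene_id}: reverse primer does not match gene at {end}")
        return self.adaptors.forward_tag + span + reverse_complement(self.adaptors.reverse_tag)


@dataclass(frozen=True)
class PrimerPanel:
    pairs: tuple[ChimericPrimerPair, ...]
    adaptors: UniversalAdaptors

    def __post_init__(self) -> None:
        ids = [p.gene_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("panel contains duplicate gene ids")

    def pair_for(self, gene_id: str) -> ChimericPrimerPair:
        for p in self.pairs:
            if p.gene_id == gene_id:
                return p
        raise KeyError(gene_id)

    @property
    def specific_tms(self) -> list[float]:
        return [t for p in self.pairs for t in (p.tm_fwd, p.tm_rev)]

    @property
    def tm_mean(self) -> float:
        return mean(self.specific_tms)

    @property
    def tm_sd(self) -> float:
        tms = self.specific_tms
        return stdev(tms) if len(tms) > 1 else 0.0

    @property
    def max_pairwise_dtm(self) -> float:
        tms = self.specific_tms
        return max(tms) - min(tms)

    def summary(self) -> dict:
        return {
            "n_pairs": len(self.pairs),
            "tm_mean": self.tm_mean,
            "tm_sd": self.tm_sd,
            "max_pairwise_dtm": self.max_pairwise_dtm,
        }


# ---------------------------------------------------------------------------
# melting temperature
# ---------------------------------------------------------------------------


@lru_cache(maxsize=200_000)
def _tm_cached(seq: str, params: TmParameters) -> float:
    return float(
        _mt.Tm_NN(
            seq,
            nn_table=params._nn_table(),
            dnac1=params.primer_nM,
            dnac2=0,
            Na=0,
            K=params.monovalent_mM,
            Tris=0,
            Mg=params.divalent_mM,
            dNTPs=0,
            saltcorr=7,
        )
    )


def melting_temperature(seq: str, tm_params: TmParameters | None = None) -> float:
    """Nearest-neighbor duplex melting temperature of ``seq`` in Celsius.

    Deterministic for fixed parameters; raises on sequences shorter than
    8 nt or containing non-ACGT characters.
    """
    seq = validate_dna(seq, name="primer", min_len=8)
    return _tm_cached(seq, tm_params or TmParameters())


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------


def enumerate_candidates(
    gene: GeneTarget,
    adaptors: UniversalAdaptors = DEFAULT_ADAPTORS,
    constraints: DesignConstraints = DEFAULT_CONSTRAINTS,
) -> list[ChimericPrimerPair]:
    """Every primer pair on ``gene`` satisfying all per-pair constraints.

    A candidate is a triple (start, fwd_len, rev_len) whose assembled PCR
    product length lies in the amplicon window, whose digested-tag length
    lies in the tag window, and whose product contains exactly one BamHI
    and one HindIII site (both inside the adaptors).  Sorted by
    (amplicon start, amplicon length, fwd_len, rev_len).
    """
    seq = gene.sequence
    lo_len, hi_len = constraints.specific_len_range
    amp_min, amp_max = constraints.amplicon_window
    tag_min, tag_max = constraints.tag_len_range
    discard = adaptors.left_discard + adaptors.right_discard
    # tag length = amplicon_len - discard; intersect the two windows
    amp_min = max(amp_min, tag_min + discard)
    amp_max = min(amp_max, tag_max + discard)
    overhead = adaptors.overhead
    span_min, span_max = amp_min - overhead, amp_max - overhead
    span_min = max(span_min, 2 * lo_len)

    if span_min > span_max or len(seq) < span_min:
        raise NoCandidatesError(
            f"gene {gene.gene_id} ({len(seq)} nt) cannot host any amplicon: "
            f"minimum genomic span is {span_min} nt for product window "
            f"[{amp_min}, {amp_max}] bp"
        )

    fwd_tag = adaptors.forward_tag
    rev_tag_rc = reverse_complement(adaptors.reverse_tag)
    bam_at = adaptors.bamhi_offset
    params = constraints.tm_params

    out: list[ChimericPrimerPair] = []
    for start in range(len(seq) - span_min + 1):
        for span in range(span_min, min(span_max, len(seq) - start) + 1):
            end = start + span
            product = fwd_tag + seq[start:end] + rev_tag_rc
            hind_at = len(product) - adaptors.hindiii_offset - 6
            # forbidden internal sites: exactly the two adaptor hexamers allowed
            if product.find(BAMHI_SITE, bam_at + 1) != -1:
                continue
            if product.find(HINDIII_SITE) != hind_at:
                continue
            for fwd_len in range(lo_len, hi_len + 1):
                for rev_len in range(lo_len, min(hi_len, span - fwd_len) + 1):
                    out.append(
                        ChimericPrimerPair(
                            gene_id=gene.gene_id,
                            fwd_specific=seq[start : start + fwd_len],
                            rev_specific=reverse_complement(seq[end - rev_len : end]),
                            amplicon_interval=(start, end),
                            amplicon_len=len(product),
                            tm_fwd=_tm_cached(seq[start : start + fwd_len], params),
                            tm_rev=_tm_cached(
                                reverse_complement(seq[end - rev_len : end]), params
                            ),
                            adaptors=adaptors,
                        )
                    )
    out.sort(
        key=lambda p: (p.amplicon_interval[0], p.amplicon_len, len(p.fwd_specific), len(p.rev_specific))
    )
    return out


# ---------------------------------------------------------------------------
# panel selection
# ---------------------------------------------------------------------------


def _candidate_key(pair: ChimericPrimerPair, center: int) -> tuple:
    """Per-gene deterministic preference: small length deviation, leftmost."""
    return (
        abs(pair.amplicon_len - center),
        pair.amplicon_interval[0],
        pair.amplicon_len,
        len(pair.fwd_specific),
        len(pair.rev_specific),
    )


def _assignment_key(pairs_by_gene: dict[str, ChimericPrimerPair], center: int) -> tuple:
    """Global tie-break: Tm spread, summed length deviation, then leftmost
    starts in lexicographic gene order."""
    chosen = [pairs_by_gene[g] for g in sorted(pairs_by_gene)]
    tms = [t for p in chosen for t in (p.tm_fwd, p.tm_rev)]
    spread = max(tms) - min(tms)
    dev = sum(abs(p.amplicon_len - center) for p in chosen)
    starts = tuple(p.amplicon_interval[0] for p in chosen)
    lens = tuple((p.amplicon_len, len(p.fwd_specific), len(p.rev_specific)) for p in chosen)
    return (round(spread, 9), dev, starts, lens)


def design_panel(
    genes: list[GeneTarget],
    adaptors: UniversalAdaptors = DEFAULT_ADAPTORS,
    constraints: DesignConstraints = DEFAULT_CONSTRAINTS,
) -> PrimerPanel:
    """Pick one primer pair per gene minimising the panel's Tm spread.

    The objective is max(Tm) - min(Tm) over all gene-specific primer parts;
    ties are broken by summed |amplicon_len - center|, then by leftmost
    amplicon starts in lexicographic gene order.  Raises
    :class:`PanelInfeasibleError` if no assignment achieves a spread within
    ``constraints.max_pairwise_dtm``.
    """
    if len(genes) < 2:
        raise ValueError("panel design needs at least two genes")
    n_control = sum(g.is_control for g in genes)
    if n_control != 1:
        raise ValueError(f"exactly one control gene required, got {n_control}")
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids in input")

    cands = {g.gene_id: enumerate_candidates(g, adaptors, constraints) for g in genes}
    empty = sorted(gid for gid, cc in cands.items() if not cc)
    if empty:
        raise NoCandidatesError(f"no feasible primer pairs for genes: {empty}")

    # Pareto set per gene for the window sweep: sorted by tm_low descending,
    # keeping strictly decreasing tm_high (interval-containment pruning).
    pareto: dict[str, list[tuple[float, float]]] = {}
    for gid, cc in cands.items():
        best: list[tuple[float, float]] = []
        hi_seen = float("inf")
        for p in sorted(cc, key=lambda p: -p.tm_low):
            if p.tm_high < hi_seen:
                best.append((p.tm_low, p.tm_high))
                hi_seen = p.tm_high
        pareto[gid] = best[::-1]  # ascending tm_low, ascending tm_high

    # sweep lower bounds: L = some candidate tm_low; H(L) = max over genes of
    # min tm_high among candidates with tm_low >= L
    all_lo = sorted({lo for plist in pareto.values() for lo, _ in plist})
    lo_arrays = {gid: [lo for lo, _ in plist] for gid, plist in pareto.items()}
    sufmin_hi: dict[str, list[float]] = {}
    for gid, plist in pareto.items():
        suf = [0.0] * len(plist)
        running = float("inf")
        for i in range(len(plist) - 1, -1, -1):
            running = min(running, plist[i][1])
            suf[i] = running
        sufmin_hi[gid] = suf

    best_spread = float("inf")
    feasible_windows: list[tuple[float, float]] = []
    for L in all_lo:
        H = -float("inf")
        ok = True
        for gid in pareto:
            i = bisect_left(lo_arrays[gid], L)
            if i == len(lo_arrays[gid]):
                ok = False
                break
            H = max(H, sufmin_hi[gid][i])
        if not ok:
            continue
        spread = H - L
        if spread < best_spread - 1e-12:
            best_spread = spread
            feasible_windows = [(L, H)]
        elif abs(spread - best_spread) <= 1e-12:
            feasible_windows.append((L, H))

    if not feasible_windows:
        raise PanelInfeasibleError("no candidate windows at all")
    if best_spread > constraints.max_pairwise_dtm + 1e-9:
        hi_caps = {gid: max(p.tm_high for p in cc) for gid, cc in cands.items()}
        lo_caps = {gid: min(p.tm_low for p in cc) for gid, cc in cands.items()}
        g_cold = min(hi_caps, key=lambda g: (hi_caps[g], g))
        g_hot = max(lo_caps, key=lambda g: (lo_caps[g], g))
        raise PanelInfeasibleError(
            f"minimum achievable Tm spread is {best_spread:.2f} C "
            f"(> {constraints.max_pairwise_dtm} C); widest-spread genes: "
            f"{g_cold} (Tm <= {hi_caps[g_cold]:.1f} C) vs "
            f"{g_hot} (Tm >= {lo_caps[g_hot]:.1f} C)"
        )

    center = constraints.amplicon_center
    best_assignment: dict[str, ChimericPrimerPair] | None = None
    best_key: tuple | None = None
    for L, H in feasible_windows:
        chosen: dict[str, ChimericPrimerPair] = {}
        for gid, cc in cands.items():
            inside = [p for p in cc if p.tm_low >= L - 1e-12 and p.tm_high <= H + 1e-12]
            chosen[gid] = min(inside, key=lambda p: _candidate_key(p, center))
        key = _assignment_key(chosen, center)
        if best_key is None or key < best_key:
            best_key = key
            best_assignment = chosen

    assert best_assignment is not None
    pairs = tuple(best_assignment[g] for g in sorted(best_assignment))
    return PrimerPanel(pairs=pairs, adaptors=adaptors)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass
class PanelValidationReport:
    per_pair: list[dict]
    violations: list[str]
    warnings: list[str]

    @property
    def passed(self) -> bool:
        return not self.violations


def validate_panel(
    panel: PrimerPanel,
    genes: list[GeneTarget],
    constraints: DesignConstraints = DEFAULT_CONSTRAINTS,
) -> PanelValidationReport:
    """Report-only check of every panel invariant against the gene set."""
    by_id = {g.gene_id: g for g in genes}
    violations: list[str] = []
    warnings: list[str] = []
    per_pair: list[dict] = []
    amp_min, amp_max = constraints.amplicon_window
    lo_len, hi_len = constraints.specific_len_range
    adaptors = panel.adaptors
    products: dict[str, str] = {}

    for p in panel.pairs:
        row = {
            "gene_id": p.gene_id,
            "tm_fwd": p.tm_fwd,
            "tm_rev": p.tm_rev,
            "amplicon_len": p.amplicon_len,
        }
        per_pair.append(row)
        if p.gene_id not in by_id:
            violations.append(f"{p.gene_id}: not present in gene set")
            continue
        if not (amp_min <= p.amplicon_len <= amp_max):
            violations.append(
                f"{p.gene_id}: amplicon length {p.amplicon_len} bp outside "
                f"[{amp_min}, {amp_max}]"
            )
        for part, label in ((p.fwd_specific, "forward"), (p.rev_specific, "reverse")):
            if not (lo_len <= len(part) <= hi_len):
                violations.append(
                    f"{p.gene_id}: {label} specific part length {len(part)} outside "
                    f"[{lo_len}, {hi_len}]"
                )
        try:
            product = p.amplicon_sequence(by_id[p.gene_id])
        except ValueError as exc:
            violations.append(str(exc))
            continue
        products[p.gene_id] = product
        bam_hits = find_all(product, BAMHI_SITE)
        hind_hits = find_all(product, HINDIII_SITE)
        if bam_hits != [adaptors.bamhi_offset]:
            violations.append(f"{p.gene_id}: BamHI sites at {bam_hits}, expected [{adaptors.bamhi_offset}]")
        want_hind = len(product) - adaptors.hindiii_offset - 6
        if hind_hits != [want_hind]:
            violations.append(f"{p.gene_id}: HindIII sites at {hind_hits}, expected [{want_hind}]")

    discard = adaptors.left_discard + adaptors.right_discard
    tags = {gid: prod[adaptors.left_discard : len(prod) - adaptors.right_discard]
            for gid, prod in products.items()}
    seen: dict[str, str] = {}
    for gid, tag in tags.items():
        if tag in seen:
            warnings.append(f"ambiguous tags: {seen[tag]} and {gid} share an identical tag sequence")
        seen[tag] = gid

    dtm = panel.max_pairwise_dtm
    if dtm > constraints.max_pairwise_dtm + 1e-9:
        violations.append(
            f"max pairwise dTm {dtm:.2f} C exceeds {constraints.max_pairwise_dtm} C"
        )
    missing = set(by_id) - {p.gene_id for p in panel.pairs}
    if missing:
        violations.append(f"genes without a primer pair: {sorted(missing)}")
    _ = discard
    return PanelValidationReport(per_pair=per_pair, violations=violations, warnings=warnings)
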