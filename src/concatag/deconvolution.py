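"""Recovery of ordered, oriented gene tags from clone-insert reads.

The inverse of the simulator: junction hexamers (GGATCC / AAGCTT) are
located exactly, the read is split into fragments that each keep both
flanking hexamers (the same shared-boundary convention the simulator
uses), orientations are inferred from the hexamer pattern, and each
fragment is assigned to a panel gene by mismatch-tolerant comparison
against the expected tag sequences in both orientations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .dna import BAMHI_SITE, HINDIII_SITE, find_all, reverse_complement
from .panel_design import GeneTarget, PrimerPanel
from .wetlab_sim import digest, make_amplicons

__all__ = [
    "OrientedTag",
    "TagReference",
    "TagCountTable",
    "Assignment",
    "find_junctions",
    "extract_tags",
    "assign_tag",
    "count_tags",
    "build_reference",
    "deconvolve_reads",
    "UNASSIGNED",
    "AMBIGUOUS",
]

UNASSIGNED = "unassigned"
AMBIGUOUS = "ambiguous"

DEFAULT_TAG_RANGE = (55, 75)  # expected tag length window incl. slack


@dataclass(frozen=True)
class OrientedTag:
    clone_id: str
    index: int
    sequence: str
    orientation: str  # F | RC | unknown
    left_junction: str | None  # GGATCC / AAGCTT / None (read edge)
    right_junction: str | None
    flagged: bool = False  # length out of expected range or malformed context

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TagReference:
    """gene_id -> expected canonical tag (forward) with both-orientation index."""

    forward: dict[str, str]
    ambiguity_warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.forward:
            raise ValueError("empty tag reference")
        seen: dict[str, str] = {}
        for gid, seq in self.forward.items():
            for s in (seq, reverse_complement(seq)):
                if s in seen and seen[s] != gid:
                    raise ValueError(
                        f"reference tags for {seen[s]} and {gid} collide exactly"
                    )
                seen[s] = gid

    @property
    def both_orientations(self) -> dict[str, str]:
        out = {}
        for gid, seq in self.forward.items():
            out[seq] = gid
            out[reverse_complement(seq)] = gid
        return out


def build_reference(
    panel: PrimerPanel,
    genes: list[GeneTarget],
    max_mismatch: int = 2,
) -> TagReference:
    """Expected canonical tag per gene, from the panel's digested amplicons.

    Reports (does not reject) reference pairs closer than the
    ``2 * max_mismatch + 1`` Hamming separation needed for unambiguous
    assignment at ``max_mismatch``.
    """
    amplicons = make_amplicons(panel, genes)
    forward = {a.gene_id: digest(a, panel.adaptors).canonical_sequence for a in amplicons}
    warnings: list[str] = []
    need = 2 * max_mismatch + 1
    gids = sorted(forward)
    for i, ga in enumerate(gids):
        for gb in gids[i + 1 :]:
            d = _pair_distance(forward[ga], forward[gb])
            d = min(d, _pair_distance(forward[ga], reverse_complement(forward[gb])))
            if d < need:
                warnings.append(
                    f"tags for {ga} and {gb} are only {d} mismatches apart "
                    f"(< {need} needed for clean assignment)"
                )
    return TagReference(forward=forward, ambiguity_warnings=tuple(warnings))


# ---------------------------------------------------------------------------
# junction finding and tag extraction
# ---------------------------------------------------------------------------


def find_junctions(read: str) -> list[tuple[int, str]]:
    """All exact occurrences of either junction hexamer, sorted by position."""
    if not read:
        raise ValueError("empty read")
    hits = [(p, BAMHI_SITE) for p in find_all(read, BAMHI_SITE)]
    hits += [(p, HINDIII_SITE) for p in find_all(read, HINDIII_SITE)]
    hits.sort()
    return hits


def _orientation_from_left(site: str | None) -> str:
    # canonical tags start with GGATCC; reverse-complemented ones with AAGCTT
    if site == BAMHI_SITE:
        return "F"
    if site == HINDIII_SITE:
        return "RC"
    return "unknown"


def _try_rescue_split(fragment: str, max_len: int) -> int | None:
    """Best internal near-hexamer position for splitting a merged fragment.

    Looks for a window within <=1 mismatch of either junction hexamer, at
    least a minimal tag away from both ends; returns its 0-based position
    or None.  Preference: fewer mismatches, then closest to the fragment
    centre.
    """
    lo = 20  # never split inside the first/last 20 bp
    best: tuple[int, int, int] | None = None
    centre = (len(fragment) - 6) / 2
    for pos in range(lo, len(fragment) - 6 - lo + 1):
        window = fragment[pos : pos + 6]
        for site in (BAMHI_SITE, HINDIII_SITE):
            mm = sum(a != b for a, b in zip(window, site))
            if mm <= 1:
                key = (mm, abs(int(pos - centre)), pos)
                if best is None or key < best:
                    best = key
    if best is None:
        return None
    return best[2]


def extract_tags(
    read: str,
    clone_id: str = "",
    tag_range: tuple[int, int] = DEFAULT_TAG_RANGE,
) -> list[OrientedTag]:
    """Split a read at junction hexamers into candidate tags.

    Every fragment keeps both flanking hexamers (shared-boundary
    convention).  Orientations alternate, anchored on the hexamer type at
    each fragment's left boundary; fragments whose junction context does
    not alternate, or whose length is outside ``tag_range``, are flagged
    rather than dropped.  Over-long fragments (putative junction-error
    merges) are rescued by one internal split at the best near-hexamer.
    """
    junctions = find_junctions(read)
    lo, hi = tag_range

    # fragment boundaries: [prev_site, next_site + 6], plus read edges
    cuts: list[tuple[int, int, str | None, str | None]] = []
    if not junctions:
        cuts.append((0, len(read), None, None))
    else:
        first_pos = junctions[0][0]
        if first_pos > 0:
            cuts.append((0, first_pos + 6, None, junctions[0][1]))
        for (p1, s1), (p2, s2) in zip(junctions, junctions[1:]):
            cuts.append((p1, p2 + 6, s1, s2))
        last_pos, last_site = junctions[-1]
        if last_pos + 6 < len(read):
            cuts.append((last_pos, len(read), last_site, None))
        if len(junctions) == 1 and first_pos == 0 and first_pos + 6 == len(read):
            cuts.append((0, len(read), junctions[0][1], None))

    # a clean read has its terminal hexamers at both edges; then the cuts
    # above double-count nothing and fragment count = junctions - 1
    if junctions and junctions[0][0] == 0 and junctions[-1][0] + 6 == len(read) and len(junctions) >= 2:
        cuts = [
            (p1, p2 + 6, s1, s2)
            for (p1, s1), (p2, s2) in zip(junctions, junctions[1:])
        ]

    # expand merged fragments once
    expanded: list[tuple[int, int, str | None, str | None, bool]] = []
    for start, end, ls, rs in cuts:
        if end - start > hi + 6 and end - start >= 2 * lo:
            split = _try_rescue_split(read[start:end], hi)
            if split is not None:
                mid_site = read[start + split : start + split + 6]
                expanded.append((start, start + split + 6, ls, mid_site, True))
                expanded.append((start + split, end, mid_site, rs, True))
                continue
        expanded.append((start, end, ls, rs, False))

    tags: list[OrientedTag] = []
    prev_right: str | None = None
    for idx, (start, end, ls, rs, rescued) in enumerate(expanded):
        frag = read[start:end]
        ori = _orientation_from_left(ls if ls in (BAMHI_SITE, HINDIII_SITE) else None)
        malformed = rescued
        if ls is not None and rs is not None and ls in (BAMHI_SITE, HINDIII_SITE) and rs in (
            BAMHI_SITE,
            HINDIII_SITE,
        ):
            if ls == rs:  # junction types must alternate around a tag
                malformed = True
                ori = "unknown"
        if prev_right is not None and ls is not None and prev_right != ls:
            malformed = True
        prev_right = rs
        out_of_range = not (lo <= len(frag) <= hi)
        tags.append(
            OrientedTag(
                clone_id=clone_id,
                index=idx,
                sequence=frag,
                orientation=ori,
                left_junction=ls,
                right_junction=rs,
                flagged=malformed or out_of_range,
            )
        )
    return tags


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _pair_distance(a: str, b: str) -> int:
    """Hamming distance for equal lengths; otherwise the best ungapped
    sliding-offset mismatch count plus the length difference."""
    if len(a) == len(b):
        return _hamming(a, b)
    short, long_ = (a, b) if len(a) < len(b) else (b, a)
    diff = len(long_) - len(short)
    best = len(short)
    for off in range(diff + 1):
        d = _hamming(short, long_[off : off + len(short)])
        if d < best:
            best = d
    return best + diff


@dataclass(frozen=True)
class Assignment:
    gene_id: str  # gene, UNASSIGNED, or AMBIGUOUS
    distance: int | None
    orientation: str  # orientation of the matched reference strand, or tag's own


def assign_tag(
    tag: OrientedTag | str,
    reference: TagReference,
    max_mismatch: int = 2,
) -> Assignment:
    """Best-match gene for a tag over both orientations of every reference.

    Assigned iff the best distance is <= ``max_mismatch`` and the margin to
    the best *other* gene is >= 2; within tolerance but without margin ->
    ambiguous; otherwise unassigned.
    """
    seq = tag.sequence if isinstance(tag, OrientedTag) else tag
    if not reference.forward:
        raise ValueError("empty tag reference")

    # exact-match fast path
    exact = reference.both_orientations.get(seq)
    if exact is not None:
        ori = "F" if seq == reference.forward[exact] else "RC"
        return Assignment(gene_id=exact, distance=0, orientation=ori)

    best_gene, best_d, best_ori = None, None, "unknown"
    second_d = None
    for gid, fwd in reference.forward.items():
        d_f = _pair_distance(seq, fwd)
        d_r = _pair_distance(seq, reverse_complement(fwd))
        d, ori = (d_f, "F") if d_f <= d_r else (d_r, "RC")
        if best_d is None or d < best_d:
            second_d = best_d
            best_gene, best_d, best_ori = gid, d, ori
        elif second_d is None or d < second_d:
            second_d = d
    assert best_d is not None
    if best_d > max_mismatch:
        return Assignment(gene_id=UNASSIGNED, distance=best_d, orientation="unknown")
    if second_d is not None and second_d - best_d < 2:
        return Assignment(gene_id=AMBIGUOUS, distance=best_d, orientation="unknown")
    return Assignment(gene_id=best_gene, distance=best_d, orientation=best_ori)


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------


@dataclass
class TagCountTable:
    """sample_id x gene_id tag-occurrence counts, plus per-sample
    unassigned/ambiguous tallies."""

    counts: dict[str, Counter] = field(default_factory=dict)
    unassigned: dict[str, int] = field(default_factory=dict)
    ambiguous: dict[str, int] = field(default_factory=dict)

    def total_extracted(self, sample_id: str) -> int:
        return (
            sum(self.counts.get(sample_id, Counter()).values())
            + self.unassigned.get(sample_id, 0)
            + self.ambiguous.get(sample_id, 0)
        )

    def get(self, sample_id: str, gene_id: str) -> int:
        return self.counts.get(sample_id, Counter()).get(gene_id, 0)

    @property
    def samples(self) -> list[str]:
        return sorted(self.counts)

    @property
    def genes(self) -> list[str]:
        return sorted({g for c in self.counts.values() for g in c})


def count_tags(
    assignments: dict[str, list[Assignment]],
    samples: list[str] | None = None,
) -> TagCountTable:
    """Aggregate per-sample assignments into a count table.

    ``assignments`` maps sample_id -> assignment list.  If ``samples`` is
    given, every assignment key must be in it (unknown labels error) and
    all listed samples appear in the table even when empty.
    """
    if samples is not None:
        unknown = sorted(set(assignments) - set(samples))
        if unknown:
            raise ValueError(f"unknown sample labels: {unknown}")
    table = TagCountTable()
    for sid in samples if samples is not None else sorted(assignments):
        table.counts[sid] = Counter()
        table.unassigned[sid] = 0
        table.ambiguous[sid] = 0
        for a in assignments.get(sid, []):
            if a.gene_id == UNASSIGNED:
                table.unassigned[sid] += 1
            elif a.gene_id == AMBIGUOUS:
                table.ambiguous[sid] += 1
            else:
                table.counts[sid][a.gene_id] += 1
    return table


def deconvolve_reads(
    reads_by_sample: dict[str, list[tuple[str, str]]],
    reference: TagReference,
    max_mismatch: int = 2,
    tag_range: tuple[int, int] = DEFAULT_TAG_RANGE,
) -> tuple[TagCountTable, dict[str, list[OrientedTag]]]:
    """Extract and assign tags for (clone_id, sequence) reads per sample."""
    assignments: dict[str, list[Assignment]] = {}
    audit: dict[str, list[OrientedTag]] = {}
    for sid, reads in reads_by_sample.items():
        alist: list[Assignment] = []
        tlist: list[OrientedTag] = []
        for clone_id, seq in reads:
            for tag in extract_tags(seq, clone_id=clone_id, tag_range=tag_range):
                tlist.append(tag)
                alist.append(assign_tag(tag, reference, max_mismatch=max_mismatch))
        assignments[sid] = alist
        audit[sid] = tlist
    table = count_tags(assignments, samples=sorted(reads_by_sample))
    return table, audit
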