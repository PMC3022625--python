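"""File formats: FASTA for sequences, TSV (tab, UTF-8, header row) for tables."""

from __future__ import annotations

import warnings
from collections import Counter
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ..deconvolution import AMBIGUOUS, UNASSIGNED, OrientedTag, TagCountTable
from ..panel_design import (
    ChimericPrimerPair,
    GeneTarget,
    PrimerPanel,
    UniversalAdaptors,
)
from ..quantify import ExpressionEstimate, QpcrRecord
from ..wetlab_sim import ExpressionProfile, SimulationResult


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs; duplicate ids error, lowercase is uppercased
    with a warning, an empty file yields an empty list with a warning."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
        return []
    out = []
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if seq != seq.upper():
            warnings.warn(f"{path}: record {rec.id} has lowercase bases; uppercasing", stacklevel=2)
            seq = seq.upper()
        out.append((rec.id, seq))
    return out


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(Path(path)), "fasta")


def read_gene_targets(path: str | Path, control: str) -> list[GeneTarget]:
    pairs = read_fasta(path)
    ids = [gid for gid, _ in pairs]
    if control not in ids:
        raise ValueError(f"control gene {control!r} not found in {path}")
    return [GeneTarget(gid, seq, is_control=(gid == control)) for gid, seq in pairs]


# ---------------------------------------------------------------------------
# panel TSV
# ---------------------------------------------------------------------------

PANEL_COLUMNS = [
    "gene_id", "fwd_full", "rev_full", "tm_fwd", "tm_rev",
    "amplicon_start", "amplicon_end", "amplicon_len",
]


def write_panel_tsv(panel: PrimerPanel, path: str | Path) -> None:
    path = Path(path)
    rows = [
        {
            "gene_id": p.gene_id,
            "fwd_full": p.fwd_full,
            "rev_full": p.rev_full,
            "tm_fwd": round(p.tm_fwd, 4),
            "tm_rev": round(p.tm_rev, 4),
            "amplicon_start": p.amplicon_interval[0],
            "amplicon_end": p.amplicon_interval[1],
            "amplicon_len": p.amplicon_len,
        }
        for p in panel.pairs
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# forward_adaptor={panel.adaptors.forward_tag}\n")
        fh.write(f"# reverse_adaptor={panel.adaptors.reverse_tag}\n")
        pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(fh, sep="\t", index=False)


def read_panel_tsv(path: str | Path) -> PrimerPanel:
    path = Path(path)
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    adaptors = UniversalAdaptors(
        forward_tag=meta.get("forward_adaptor", ""),
        reverse_tag=meta.get("reverse_adaptor", ""),
    )
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: panel TSV missing columns {sorted(missing)}")
    pairs = []
    n_fwd = len(adaptors.forward_tag)
    n_rev = len(adaptors.reverse_tag)
    for row in df.itertuples(index=False):
        fwd_full, rev_full = str(row.fwd_full), str(row.rev_full)
        if not fwd_full.startswith(adaptors.forward_tag):
            raise ValueError(f"{path}: {row.gene_id} fwd_full does not begin with the adaptor")
        if not rev_full.startswith(adaptors.reverse_tag):
            raise ValueError(f"{path}: {row.gene_id} rev_full does not begin with the adaptor")
        pairs.append(
            ChimericPrimerPair(
                gene_id=str(row.gene_id),
                fwd_specific=fwd_full[n_fwd:],
                rev_specific=rev_full[n_rev:],
                amplicon_interval=(int(row.amplicon_start), int(row.amplicon_end)),
                amplicon_len=int(row.amplicon_len),
                tm_fwd=float(row.tm_fwd),
                tm_rev=float(row.tm_rev),
                adaptors=adaptors,
            )
        )
    return PrimerPanel(pairs=tuple(pairs), adaptors=adaptors)


def write_panel_fasta(panel: PrimerPanel, path: str | Path) -> None:
    records = []
    for p in panel.pairs:
        records.append((f"{p.gene_id}_fwd", p.fwd_full))
        records.append((f"{p.gene_id}_rev", p.rev_full))
    write_fasta(records, path)


# ---------------------------------------------------------------------------
# profiles / truth / counts
# ---------------------------------------------------------------------------


def write_profiles_tsv(profiles: list[ExpressionProfile], path: str | Path) -> None:
    rows = [
        {"sample_id": p.sample_id, "gene_id": g, "weight": w}
        for p in profiles
        for g, w in p.weights.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_profiles_tsv(path: str | Path) -> list[ExpressionProfile]:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "gene_id", "weight"):
        if col not in df.columns:
            raise ValueError(f"{path}: profiles TSV missing column {col!r}")
    profiles = []
    for sid, grp in df.groupby("sample_id", sort=True):
        weights = dict(zip(grp["gene_id"].astype(str), grp["weight"].astype(float)))
        profiles.append(ExpressionProfile(str(sid), weights))
    return profiles


def write_truth_tsv(result: SimulationResult, path: str | Path) -> None:
    rows = [
        {"clone_id": cid, "position": pos, "gene_id": gid, "orientation": ori}
        for cid, pos, gid, ori in result.truth_rows()
    ]
    pd.DataFrame(rows, columns=["clone_id", "position", "gene_id", "orientation"]).to_csv(
        path, sep="\t", index=False
    )


def write_reads_fasta(result: SimulationResult, path: str | Path) -> None:
    write_fasta([(r.clone_id, r.sequence) for r in result.reads], path)


def write_counts_tsv(table: TagCountTable, path: str | Path) -> None:
    rows = []
    for sid in sorted(table.counts):
        for gid in sorted(table.counts[sid]):
            rows.append({"sample_id": sid, "gene_id": gid, "count": table.counts[sid][gid]})
        rows.append({"sample_id": sid, "gene_id": UNASSIGNED, "count": table.unassigned.get(sid, 0)})
        rows.append({"sample_id": sid, "gene_id": AMBIGUOUS, "count": table.ambiguous.get(sid, 0)})
    pd.DataFrame(rows, columns=["sample_id", "gene_id", "count"]).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> TagCountTable:
    df = pd.read_csv(path, sep="\t")
    table = TagCountTable()
    for row in df.itertuples(index=False):
        sid, gid, count = str(row.sample_id), str(row.gene_id), int(row.count)
        table.counts.setdefault(sid, Counter())
        table.unassigned.setdefault(sid, 0)
        table.ambiguous.setdefault(sid, 0)
        if gid == UNASSIGNED:
            table.unassigned[sid] = count
        elif gid == AMBIGUOUS:
            table.ambiguous[sid] = count
        else:
            table.counts[sid][gid] = count
    return table


def write_audit_tsv(audit: dict[str, list[OrientedTag]], path: str | Path) -> None:
    rows = [
        {
            "sample_id": sid,
            "clone_id": t.clone_id,
            "index": t.index,
            "length": t.length,
            "orientation": t.orientation,
            "flagged": t.flagged,
        }
        for sid, tags in sorted(audit.items())
        for t in tags
    ]
    pd.DataFrame(
        rows, columns=["sample_id", "clone_id", "index", "length", "orientation", "flagged"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# quantification tables
# ---------------------------------------------------------------------------

ESTIMATE_COLUMNS = [
    "gene_id", "count_t", "control_t", "count_u", "control_u",
    "ratio", "log2_ratio", "ci_low", "ci_high", "call", "corrected",
]


def write_estimates_tsv(estimates: list[ExpressionEstimate], path: str | Path) -> None:
    rows = [{c: getattr(e, c) for c in ESTIMATE_COLUMNS} for e in estimates]
    pd.DataFrame(rows, columns=ESTIMATE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_qpcr_tsv(path: str | Path) -> list[QpcrRecord]:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "gene_id", "ct"):
        if col not in df.columns:
            raise ValueError(f"{path}: qPCR TSV missing column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            QpcrRecord(
                sample_id=str(row.sample_id),
                gene_id=str(row.gene_id),
                ct=float(row.ct),
                replicate=int(getattr(row, "replicate", 0)),
            )
        )
    return records


def write_qpcr_tsv(records: list[QpcrRecord], path: str | Path) -> None:
    rows = [
        {"sample_id": r.sample_id, "gene_id": r.gene_id, "replicate": r.replicate, "ct": r.ct}
        for r in records
    ]
    pd.DataFrame(rows, columns=["sample_id", "gene_id", "replicate", "ct"]).to_csv(
        path, sep="\t", index=False
    )


def write_concordance_tsv(rows: list[dict], path: str | Path) -> None:
    # column names surface the dCT sign convention: dCT = CT(control) - CT(target)
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "tag_ratio", "tag_call", "qpcr_fold", "qpcr_call", "agree"],
    ).rename(columns={"qpcr_fold": "qpcr_fold_2^ddct_ctrl_minus_target"})
    df.to_csv(path, sep="\t", index=False)
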