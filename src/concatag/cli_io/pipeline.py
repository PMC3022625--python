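"""End-to-end orchestration: design -> simulate -> deconvolve -> quantify."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

from .. import datasets
from ..deconvolution import build_reference, deconvolve_reads
from ..panel_design import GeneTarget, PrimerPanel, design_panel, validate_panel
from ..quantify import concordance, qpcr_fold_changes, relative_expression
from ..wetlab_sim import ExpressionProfile, simulate_sample
from .config import RunConfig
from . import io as cio


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    out_dir: Path
    panel: PrimerPanel
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_end_to_end(
    config: RunConfig,
    out_dir: str | Path,
    genes: list[GeneTarget] | None = None,
    profiles: tuple[ExpressionProfile, ExpressionProfile] | None = None,
) -> PipelineResult:
    """Run the whole pipeline, writing every artifact plus a checksummed
    manifest; identical config and seed give identical checksums.

    Inputs default to the packaged synthetic fixture (or the paths in the
    config, when set).  Each stage failure aborts with a
    :class:`StageError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    # -- inputs ------------------------------------------------------------
    try:
        if genes is None:
            if config.genes_fasta:
                genes = cio.read_gene_targets(config.genes_fasta, config.control_gene)
            else:
                genes = datasets.synthetic_gene_targets(
                    control=config.control_gene,
                    adaptors=config.adaptors(),
                    constraints=config.constraints(),
                )
        if profiles is None:
            if config.profiles_tsv:
                loaded = cio.read_profiles_tsv(config.profiles_tsv)
                if len(loaded) != 2:
                    raise ValueError(f"expected 2 sample profiles, got {len(loaded)}")
                profiles = (loaded[0], loaded[1])
            else:
                profiles = datasets.two_condition_profiles(
                    gene_ids=tuple(g.gene_id for g in genes),
                    control=config.control_gene,
                    seed=config.seed,
                )
        cio.write_fasta([(g.gene_id, g.sequence) for g in genes], out / "genes.fasta")
        outputs["genes.fasta"] = out / "genes.fasta"
        cio.write_profiles_tsv(list(profiles), out / "profiles.tsv")
        outputs["profiles.tsv"] = out / "profiles.tsv"
    except StageError:
        raise
    except Exception as exc:
        raise StageError("inputs", exc) from exc

    # -- design ------------------------------------------------------------
    try:
        panel = design_panel(genes, config.adaptors(), config.constraints())
        report = validate_panel(panel, genes, config.constraints())
        if not report.passed:
            raise ValueError(f"designed panel failed validation: {report.violations}")
        cio.write_panel_tsv(panel, out / "panel.tsv")
        cio.write_panel_fasta(panel, out / "panel_primers.fasta")
        outputs["panel.tsv"] = out / "panel.tsv"
        outputs["panel_primers.fasta"] = out / "panel_primers.fasta"
    except Exception as exc:
        raise StageError("design", exc) from exc

    # -- simulate ----------------------------------------------------------
    try:
        results = {}
        for i, profile in enumerate(profiles):
            sim_cfg = config.sim_config(seed=config.seed + i)
            res = simulate_sample(profile.sample_id, panel, genes, profile, sim_cfg)
            results[profile.sample_id] = res
            cio.write_reads_fasta(res, out / f"reads_{profile.sample_id}.fasta")
            cio.write_truth_tsv(res, out / f"truth_{profile.sample_id}.tsv")
            outputs[f"reads_{profile.sample_id}.fasta"] = out / f"reads_{profile.sample_id}.fasta"
            outputs[f"truth_{profile.sample_id}.tsv"] = out / f"truth_{profile.sample_id}.tsv"
    except Exception as exc:
        raise StageError("simulate", exc) from exc

    # -- deconvolve --------------------------------------------------------
    try:
        reference = build_reference(panel, genes, max_mismatch=config.max_mismatch)
        reads_by_sample = {
            sid: [(r.clone_id, r.sequence) for r in res.reads] for sid, res in results.items()
        }
        table, audit = deconvolve_reads(
            reads_by_sample,
            reference,
            max_mismatch=config.max_mismatch,
            tag_range=tuple(config.tag_slack_range),
        )
        cio.write_counts_tsv(table, out / "counts.tsv")
        cio.write_audit_tsv(audit, out / "tag_audit.tsv")
        outputs["counts.tsv"] = out / "counts.tsv"
        outputs["tag_audit.tsv"] = out / "tag_audit.tsv"
    except Exception as exc:
        raise StageError("deconvolve", exc) from exc

    # -- quantify + compare ------------------------------------------------
    try:
        treated_id, untreated_id = profiles[0].sample_id, profiles[1].sample_id
        estimates = relative_expression(
            table, treated_id, untreated_id, config.control_gene, ci_level=config.ci_level
        )
        cio.write_estimates_tsv(estimates, out / "estimates.tsv")
        outputs["estimates.tsv"] = out / "estimates.tsv"

        qpcr = datasets.qpcr_records_from_profiles(
            profiles, control=config.control_gene, ct_sd=config.qpcr_ct_sd, seed=config.seed + 101
        )
        cio.write_qpcr_tsv(qpcr, out / "qpcr_ct.tsv")
        outputs["qpcr_ct.tsv"] = out / "qpcr_ct.tsv"
        folds = qpcr_fold_changes(qpcr, treated_id, untreated_id, config.control_gene)
        rows = concordance(estimates, folds, fold_threshold=config.fold_threshold)
        cio.write_concordance_tsv(rows, out / "concordance.tsv")
        outputs["concordance.tsv"] = out / "concordance.tsv"
    except Exception as exc:
        raise StageError("quantify", exc) from exc

    # -- manifest ----------------------------------------------------------
    config.save(out / "resolved_config.yaml")
    outputs["resolved_config.yaml"] = out / "resolved_config.yaml"
    manifest = {
        "seed": config.seed,
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(out_dir=out, panel=panel, manifest=manifest)
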