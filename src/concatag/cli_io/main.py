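"""Command-line interface.

Exit codes: 0 success, 2 user error (bad arguments), 3 data error
(malformed input files or infeasible design).
"""

from __future__ import annotations

import functools
import sys
from pathlib import Path

import click

from ..deconvolution import build_reference, deconvolve_reads
from ..dna import AlphabetError
from ..panel_design import (
    NoCandidatesError,
    PanelInfeasibleError,
    design_panel,
    validate_panel,
)
from ..quantify import qpcr_fold_changes, relative_expression, concordance
from ..wetlab_sim import simulate_sample
from .config import RunConfig
from .pipeline import StageError, run_end_to_end
from . import io as cio

_DATA_ERRORS = (
    AlphabetError,
    NoCandidatesError,
    PanelInfeasibleError,
    StageError,
    ValueError,
    FileNotFoundError,
)


def _data_errors_exit_3(fn):
    @functools.wraps(fn)
    def wrapper(*args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except _DATA_ERRORS as exc:
            click.echo(f"error: {exc}", err=True)
            sys.exit(3)

    return wrapper


def _load_config(config_path: str | None, seed: int | None) -> RunConfig:
    cfg = RunConfig.load(config_path) if config_path else RunConfig()
    if seed is not None:
        cfg = cfg.with_overrides(seed=seed)
    return cfg


@click.group()
@click.option("--verbose", is_flag=True, default=False, help="Chatty progress output.")
@click.pass_context
def main(ctx, verbose):
    """Concatemer-tag expression profiling toolkit."""
    ctx.ensure_object(dict)
    ctx.obj["verbose"] = verbose


@main.command()
@click.option("--genes", "genes_path", required=True, type=click.Path(exists=True))
@click.option("--control", "control", required=True, help="Internal-control gene id.")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out", "out_prefix", required=True, help="Output path prefix.")
@_data_errors_exit_3
def design(genes_path, control, config_path, out_prefix):
    """Design a multiplex chimeric-primer panel from a gene FASTA."""
    cfg = _load_config(config_path, None)
    genes = cio.read_gene_targets(genes_path, control)
    panel = design_panel(genes, cfg.adaptors(), cfg.constraints())
    report = validate_panel(panel, genes, cfg.constraints())
    cio.write_panel_tsv(panel, f"{out_prefix}.panel.tsv")
    cio.write_panel_fasta(panel, f"{out_prefix}.primers.fasta")
    s = panel.summary()
    click.echo(
        f"designed {s['n_pairs']} pairs; Tm {s['tm_mean']:.1f}+/-{s['tm_sd']:.1f} C, "
        f"max pairwise dTm {s['max_pairwise_dtm']:.2f} C; "
        f"validation {'PASS' if report.passed else 'FAIL'}"
    )
    if not report.passed:
        for v in report.violations:
            click.echo(f"violation: {v}", err=True)
        sys.exit(3)


@main.command()
@click.option("--panel", "panel_path", required=True, type=click.Path(exists=True))
@click.option("--genes", "genes_path", required=True, type=click.Path(exists=True))
@click.option("--profiles", "profiles_path", required=True, type=click.Path(exists=True))
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--out", "out_dir", required=True, type=click.Path())
@_data_errors_exit_3
def simulate(panel_path, genes_path, profiles_path, config_path, seed, out_dir):
    """Simulate the protocol for every sample profile."""
    cfg = _load_config(config_path, seed)
    panel = cio.read_panel_tsv(panel_path)
    control = cfg.control_gene
    genes = cio.read_gene_targets(genes_path, control)
    profiles = cio.read_profiles_tsv(profiles_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, profile in enumerate(profiles):
        res = simulate_sample(
            profile.sample_id, panel, genes, profile, cfg.sim_config(seed=cfg.seed + i)
        )
        cio.write_reads_fasta(res, out / f"reads_{profile.sample_id}.fasta")
        cio.write_truth_tsv(res, out / f"truth_{profile.sample_id}.tsv")
        click.echo(f"{profile.sample_id}: {len(res.reads)} clones (seed {cfg.seed + i})")


@main.command()
@click.option("--reads", "reads_paths", required=True,
              help="Comma-separated sample=FASTA entries, or plain FASTA paths.")
@click.option("--panel", "panel_path", required=True, type=click.Path(exists=True))
@click.option("--genes", "genes_path", required=True, type=click.Path(exists=True))
@click.option("--control", default="ACT1", show_default=True)
@click.option("--max-mismatch", type=int, default=2, show_default=True)
@click.option("--out", "out_dir", required=True, type=click.Path())
@_data_errors_exit_3
def deconvolve(reads_paths, panel_path, genes_path, control, max_mismatch, out_dir):
    """Extract, assign and count gene tags from clone reads."""
    panel = cio.read_panel_tsv(panel_path)
    genes = cio.read_gene_targets(genes_path, control)
    reference = build_reference(panel, genes, max_mismatch=max_mismatch)
    reads_by_sample = {}
    for entry in reads_paths.split(","):
        if "=" in entry:
            sid, path = entry.split("=", 1)
        else:
            path = entry
            sid = Path(entry).stem.removeprefix("reads_")
        reads_by_sample[sid] = cio.read_fasta(path)
    table, audit = deconvolve_reads(reads_by_sample, reference, max_mismatch=max_mismatch)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cio.write_counts_tsv(table, out / "counts.tsv")
    cio.write_audit_tsv(audit, out / "tag_audit.tsv")
    for sid in table.samples:
        click.echo(
            f"{sid}: {sum(table.counts[sid].values())} assigned, "
            f"{table.unassigned[sid]} unassigned, {table.ambiguous[sid]} ambiguous"
        )


@main.command()
@click.option("--counts", "counts_path", required=True, type=click.Path(exists=True))
@click.option("--treated", required=True)
@click.option("--untreated", required=True)
@click.option("--control", required=True)
@click.option("--ci-level", type=float, default=0.95, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
@_data_errors_exit_3
def quantify(counts_path, treated, untreated, control, ci_level, out_path):
    """Control-normalized relative expression from a counts table."""
    table = cio.read_counts_tsv(counts_path)
    estimates = relative_expression(table, treated, untreated, control, ci_level=ci_level)
    cio.write_estimates_tsv(estimates, out_path)
    n_changed = sum(e.call != "unchanged" for e in estimates)
    click.echo(f"{len(estimates)} genes, {n_changed} called changed")


@main.command()
@click.option("--estimates", "estimates_path", required=True, type=click.Path(exists=True))
@click.option("--qpcr", "qpcr_path", required=True, type=click.Path(exists=True))
@click.option("--treated", required=True)
@click.option("--untreated", required=True)
@click.option("--control", required=True)
@click.option("--fold-threshold", type=float, default=1.5, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
@_data_errors_exit_3
def compare(estimates_path, qpcr_path, treated, untreated, control, fold_threshold, out_path):
    """Concordance of tag-count calls against comparative-CT qPCR."""
    import pandas as pd

    from ..quantify import ExpressionEstimate

    df = pd.read_csv(estimates_path, sep="\t")
    estimates = [
        ExpressionEstimate(**{k: row[k] for k in cio.ESTIMATE_COLUMNS}) for _, row in df.iterrows()
    ]
    records = cio.read_qpcr_tsv(qpcr_path)
    folds = qpcr_fold_changes(records, treated, untreated, control)
    rows = concordance(estimates, folds, fold_threshold=fold_threshold)
    cio.write_concordance_tsv(rows, out_path)
    n_agree = sum(r["agree"] for r in rows)
    click.echo(f"{n_agree}/{len(rows)} genes concordant")


@main.command("run-all")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--out", "out_dir", required=True, type=click.Path())
@_data_errors_exit_3
def run_all(config_path, seed, out_dir):
    """Design, simulate, deconvolve, quantify and compare in one run."""
    cfg = _load_config(config_path, seed)
    result = run_end_to_end(cfg, out_dir)
    click.echo(f"wrote {len(result.manifest['outputs'])} artifacts to {result.out_dir}")


if __name__ == "__main__":
    main()
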