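"""Run configuration: one YAML file holding every module's defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

from ..panel_design import (
    DEFAULT_ADAPTORS,
    DesignConstraints,
    TmParameters,
    UniversalAdaptors,
)
from ..wetlab_sim import SimConfig


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration for an end-to-end run.

    Round-trips losslessly through YAML (`to_dict`/`from_dict`); every run
    log records the resolved config together with the seed actually used.
    """

    seed: int = 0
    forward_adaptor: str = DEFAULT_ADAPTORS.forward_tag
    reverse_adaptor: str = DEFAULT_ADAPTORS.reverse_tag
    specific_len_range: tuple[int, int] = (16, 20)
    amplicon_center: int = 85
    amplicon_tol: int = 7
    tag_len_range: tuple[int, int] = (60, 70)
    max_pairwise_dtm: float = 5.0
    tm_table: str = "santalucia2004"
    tm_primer_nM: float = 200.0
    tm_monovalent_mM: float = 50.0
    tm_divalent_mM: float = 5.0
    n_clones: int = 300
    tag_pool_depth: int = 100_000
    n_ligation_products: int = 2000
    stop_prob: float = 0.08
    seq_error_rate: float = 0.0
    size_window: tuple[int, int] = (500, 1200)
    max_mismatch: int = 2
    tag_slack_range: tuple[int, int] = (55, 75)
    ci_level: float = 0.95
    fold_threshold: float = 1.5
    qpcr_ct_sd: float = 0.2
    genes_fasta: str | None = None
    profiles_tsv: str | None = None
    control_gene: str = "ACT1"

    # -- derived module configs -------------------------------------------

    def adaptors(self) -> UniversalAdaptors:
        return UniversalAdaptors(self.forward_adaptor, self.reverse_adaptor)

    def constraints(self) -> DesignConstraints:
        return DesignConstraints(
            specific_len_range=tuple(self.specific_len_range),
            amplicon_center=self.amplicon_center,
            amplicon_tol=self.amplicon_tol,
            tag_len_range=tuple(self.tag_len_range),
            max_pairwise_dtm=self.max_pairwise_dtm,
            tm_params=TmParameters(
                table=self.tm_table,
                primer_nM=self.tm_primer_nM,
                monovalent_mM=self.tm_monovalent_mM,
                divalent_mM=self.tm_divalent_mM,
            ),
        )

    def sim_config(self, seed: int | None = None) -> SimConfig:
        return SimConfig(
            n_clones=self.n_clones,
            tag_pool_depth=self.tag_pool_depth,
            n_ligation_products=self.n_ligation_products,
            stop_prob=self.stop_prob,
            seq_error_rate=self.seq_error_rate,
            size_window=tuple(self.size_window),
            rng_seed=self.seed if seed is None else seed,
        )

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("specific_len_range", "tag_len_range", "size_window", "tag_slack_range"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("specific_len_range", "tag_len_range", "size_window", "tag_slack_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

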