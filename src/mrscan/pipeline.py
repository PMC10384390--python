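"""End-to-end orchestration: select -> harmonize -> estimate -> sensitivity.

Every run writes its resolved configuration and a command history line next
to the result tables, so feeding the resolved config back reproduces all
tables bit-identically for the same seed.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import MRScanError
from .estimators import run_mr
from .harmonization import (DEFAULT_AMBIGUITY_WINDOW, DEFAULT_MODE,
                            HarmonizedSet, harmonize_set)
from .instruments import (DEFAULT_CLUMP_R2, DEFAULT_CLUMP_WINDOW,
                          DEFAULT_P_THRESHOLD, DEFAULT_PROXY_R2,
                          apply_proxies, select_instruments)
from .ld import LDProvider
from .sensitivity import SensitivityReport, sensitivity_report
from .sumstats import SummaryStatsSet, write_results
from .viz import render_diagnostics

logger = logging.getLogger(__name__)

DEFAULT_METHODS = ("ivw_re", "egger", "weighted_median", "weighted_mode")


@dataclass
class RunConfig:
    """Declarative description of one MR analysis run."""

    seed: int = 0
    methods: tuple[str, ...] = DEFAULT_METHODS
    p_threshold: float = DEFAULT_P_THRESHOLD
    mhc_exclude: bool = True
    clump_r2: float = DEFAULT_CLUMP_R2
    clump_window_bp: int = DEFAULT_CLUMP_WINDOW
    proxy_r2_min: float = DEFAULT_PROXY_R2
    harmonize_mode: int = DEFAULT_MODE
    ambiguity_window: float = DEFAULT_AMBIGUITY_WINDOW
    steiger: bool = True
    steiger_alpha: float = 0.05
    n_boot: int = 1000
    figure_format: str = "png"
    figure_dpi: int = 150
    figure_size: tuple[float, float] = (6.0, 5.0)
    # optional file inputs, used by the CLI
    exposure_path: Optional[str] = None
    outcome_path: Optional[str] = None
    ld_path: Optional[str] = None
    column_map: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        d["figure_size"] = list(self.figure_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        if "figure_size" in d:
            d["figure_size"] = tuple(d["figure_size"])
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class RunBundle:
    """Everything one pipeline run produced."""

    mr_results: list
    sensitivity: SensitivityReport
    harmonized: HarmonizedSet
    selection: object
    tables: dict[str, Path] = field(default_factory=dict)
    figures: dict[str, dict[str, Path]] = field(default_factory=dict)
    config_path: Optional[Path] = None


def _stage(name: str):
    """Re-raise stage errors with stage-tagged context."""
    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, MRScanError):
                raise type(exc)(f"[stage:{name}] {exc}") from exc
            return False
    return _ctx()


def run_pipeline(
    config: RunConfig,
    exposure: SummaryStatsSet,
    outcome: SummaryStatsSet,
    ld: Optional[LDProvider] = None,
    out_dir: Optional[str | Path] = None,
) -> RunBundle:
    """Execute the full single-pair analysis and (optionally) write the bundle.

    The bundle directory contains four tables (MR summary, sensitivity
    blocks, harmonization audit, instrument-selection audit), four figures
    with their plot-data TSVs, the resolved config and a command-history
    line.
    """
    with _stage("select"):
        instruments, selection = select_instruments(
            exposure, outcome=outcome, ld=ld, p_threshold=config.p_threshold,
            mhc_exclude=config.mhc_exclude, r2_max=config.clump_r2,
            window_bp=config.clump_window_bp, proxy_r2_min=config.proxy_r2_min)
    with _stage("harmonize"):
        out = outcome
        if selection.proxies:
            out = apply_proxies(outcome, selection.proxies, exposure)
        h = harmonize_set(instruments, out, mode=config.harmonize_mode,
                          ambiguity_window=config.ambiguity_window)
    with _stage("sensitivity"):
        sens = sensitivity_report(h, steiger_alpha=config.steiger_alpha,
                                  run_steiger=config.steiger)
    with _stage("estimate"):
        results = run_mr(h, list(config.methods), n_boot=config.n_boot,
                         seed=config.seed)

    bundle = RunBundle(mr_results=results, sensitivity=sens, harmonized=h,
                       selection=selection)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        bundle.tables = write_bundle_tables(bundle, out_dir)
        with _stage("figures"):
            bundle.figures = render_diagnostics(
                results, sens, h, out_dir, format=config.figure_format,
                dpi=config.figure_dpi, size=config.figure_size)
        bundle.config_path = write_resolved_config(config, out_dir)
    return bundle


def write_bundle_tables(bundle: RunBundle, out_dir: Path) -> dict[str, Path]:
    tables: dict[str, Path] = {}
    mr_path = out_dir / "mr_results.tsv"
    write_results(bundle.mr_results, mr_path, "tsv")
    tables["mr_results"] = mr_path

    sens = bundle.sensitivity
    sens_rows = [{
        "q_stat": sens.q_stat, "q_df": sens.q_df, "q_pval": sens.q_pval,
        "egger_intercept": sens.egger_intercept,
        "egger_intercept_se": sens.egger_intercept_se,
        "egger_intercept_pval": sens.egger_intercept_pval,
    }]
    sens_path = out_dir / "sensitivity.tsv"
    write_results(sens_rows, sens_path, "tsv")
    tables["sensitivity"] = sens_path

    steiger_path = out_dir / "steiger.tsv"
    write_results(sens.steiger, steiger_path, "tsv")
    tables["steiger"] = steiger_path

    audit_path = out_dir / "harmonization_audit.tsv"
    bundle.harmonized.audit_table().to_csv(audit_path, sep="\t", index=False)
    tables["harmonization_audit"] = audit_path

    sel = bundle.selection
    sel_rows = ([{"snp_id": snp, "status": "kept", "detail": ""}
                 for snp in sel.kept]
                + [{"snp_id": snp, "status": "removed", "detail": reason}
                   for snp, reason in sel.removed]
                + [{"snp_id": orig, "status": "proxied",
                    "detail": f"{proxy}:r2={r2}"}
                   for orig, proxy, r2 in sel.proxies])
    sel_path = out_dir / "instrument_selection.tsv"
    write_results(sel_rows, sel_path, "tsv")
    tables["instrument_selection"] = sel_path
    return tables


def write_resolved_config(config: RunConfig, out_dir: Path) -> Path:
    path = out_dir / "resolved_config.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    history = out_dir / "command_history.txt"
    with open(history, "a") as fh:
        fh.write(" ".join(sys.argv) + "\n")
    return path


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})
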