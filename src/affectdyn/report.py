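"""Publication-style outputs and the end-to-end pipeline driver.

Coefficient tables carry three blocks (HOMEBASE, VARIANCE, AUTOREGRESSIVE
slope); group-contrast rows are bolded only when the frequentist test is
significant AND the Bayesian credible interval excludes zero.  Density plots
show the group-wise distributions of per-person posterior means.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from affectdyn import bayes as bayes_mod
from affectdyn import preprocess as prep
from affectdyn import simulate as sim
from affectdyn.data import read_long_csv, write_long_csv
from affectdyn.freq import FreqFit, GroupDesign, fit_mels, wald_table

logger = logging.getLogger(__name__)

_BLOCK_COMPONENT = {"HOMEBASE": "homebase", "VARIANCE": "logvar", "AUTOREGRESSIVE": "autoreg"}


class PipelineError(RuntimeError):
    """Raised with a stage tag when any pipeline stage fails."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class ReportBundle:
    """Everything the report stage produces."""

    table: pd.DataFrame
    table_text: str
    density_data: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def render_tables(freq: FreqFit, bayes_summary: pd.DataFrame,
                  J_per_equation: Optional[int] = None, p_threshold: float = 0.05) -> pd.DataFrame:
    """Merge the Wald table with the Bayesian contrast summary.

    Adds ``supported`` (Bayesian interval excludes 0) and ``bold``
    (frequentist p < threshold AND supported) columns on the contrast rows.
    """
    table = wald_table(freq, J_per_equation)
    freq_contrasts = set(freq.design.dummy_names)
    bayes_contrasts = set(bayes_summary["contrast"].unique())
    if freq_contrasts != bayes_contrasts:
        raise ValueError(
            f"mismatched group sets: frequentist {sorted(freq_contrasts)} vs Bayesian {sorted(bayes_contrasts)}"
        )
    key = {(row["contrast"], row["component"]): bool(row["supported"]) for _, row in bayes_summary.iterrows()}
    supported, bold = [], []
    for _, row in table.iterrows():
        name = row["name"]
        comp = _BLOCK_COMPONENT[str(row["block"])]
        if name.endswith(":intercept"):
            supported.append(pd.NA)
            bold.append(False)
        else:
            dummy = name.split(":", 1)[1]
            sup = key[(dummy, comp)]
            supported.append(sup)
            bold.append(bool(sup and row["p"] < p_threshold))
    out = table.copy()
    out["supported"] = supported
    out["bold"] = bold
    return out


def _fmt_p(p: float) -> str:
    if np.isnan(p):
        return ""
    return "<.001" if p < 0.001 else f"{p:.3f}".lstrip("0").replace("0.", ".")


def format_table_text(table: pd.DataFrame) -> str:
    """Plain-text rendering: 2-decimal coefficients, 3-decimal SEs, p as '<.001'.

    Bolded rows (both frameworks agree) are marked with ``**``.
    """
    lines = [f"{'':18s}{'Coeff.':>8s}{'SE':>8s}{'Stat':>8s}{'df':>6s}{'p':>8s}"]
    for block in ("HOMEBASE", "VARIANCE", "AUTOREGRESSIVE"):
        lines.append(f"For {block}")
        for _, row in table[table["block"] == block].iterrows():
            df = "" if pd.isna(row["df"]) else f"{int(row['df'])}"
            mark = "**" if row.get("bold", False) else "  "
            lines.append(
                f"{mark}{row['name']:<16s}{row['coeff']:>8.2f}{row['se']:>8.3f}"
                f"{row['stat']:>8.2f}{df:>6s}{_fmt_p(row['p']):>8s}"
            )
    return "\n".join(lines)


def render_density_plots(person_means: pd.DataFrame, outdir, bw_method: str = "scott",
                         grid_size: int = 256, file_format: str = "svg") -> dict:
    """Group-overlaid kernel density plots of the per-person posterior means.

    One vector-format panel per component.  A group with a single person is
    drawn as a rug (a density estimate needs >= 2 points) with a warning.
    Returns the numeric density grids keyed by component for verification.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    components = ["homebase", "within_variance", "autocorrelation"]
    groups = sorted(person_means["group"].unique())
    out: dict[str, dict] = {}
    for comp in components:
        vals_all = person_means[comp].to_numpy(float)
        lo, hi = vals_all.min(), vals_all.max()
        pad = 0.25 * (hi - lo + 1e-9)
        grid = np.linspace(lo - pad, hi + pad, grid_size)
        fig, ax = plt.subplots(figsize=(5, 3.2))
        dens: dict[str, np.ndarray] = {}
        for g in groups:
            vals = person_means.loc[person_means["group"] == g, comp].to_numpy(float)
            if len(vals) < 2 or np.allclose(vals, vals[0]):
                logger.warning("render_density_plots: group %s has %d usable value(s) for %s; drawing a rug",
                               g, len(vals), comp)
                ax.plot(vals, np.zeros_like(vals), "|", markersize=14, label=g)
                continue
            kde = sps.gaussian_kde(vals, bw_method=bw_method)
            y = kde(grid)
            dens[g] = y
            ax.plot(grid, y, label=g)
        ax.set_xlabel(comp.replace("_", " "))
        ax.set_ylabel("density")
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = outdir / f"density_{comp}.{file_format}"
        fig.savefig(path)
        plt.close(fig)
        out[comp] = {"path": str(path), "grid": grid, "densities": dens,
                     "bandwidth_rule": bw_method}
    return out


# ---------------------------------------------------------------------------
# pipeline


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-tagged with the stage name
                raise PipelineError(name, str(exc)) from exc
        return inner
    return wrap


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: Mapping, outdir, seed: Optional[int] = None) -> ReportBundle:
    """simulate (optional) -> preprocess -> fit-freq -> fit-bayes -> report.

    Every stage logs its inputs and seeds; rerunning with the same config is
    bit-identical for the frequentist outputs and draw-identical for the
    Bayesian outputs.  Any stage failure raises :class:`PipelineError` with a
    stage tag.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("affectdyn")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_pipeline_inner(config, outdir, seed)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_pipeline_inner(config: Mapping, outdir: Path, seed: Optional[int]) -> ReportBundle:
    import affectdyn

    master_seed = seed if seed is not None else int(config.get("seed", 0))
    logger.info("pipeline start: seed=%d, affectdyn version %s", master_seed, affectdyn.__version__)
    paths: dict[str, str] = {}

    @_stage("simulate")
    def stage_simulate():
        if "data" in config:
            logger.info("simulate: skipped, loading %s", config["data"])
            return read_long_csv(config["data"])
        frame = sim.simulate_study(config["simulate"], seed=master_seed)
        p = outdir / "simulated.csv"
        write_long_csv(frame, p)
        paths["simulated"] = str(p)
        return frame

    @_stage("preprocess")
    def stage_preprocess(frame):
        outcome = config.get("outcome", "distress")
        series = prep.extract_outcome(frame, outcome)
        rules = config.get("exclusion_rules", ("zero_variance", "linear_trend"))
        series, excl = prep.exclude_participants(series, rules=rules)
        if series.empty:
            raise ValueError("all participants excluded")
        lagged = prep.build_lagged(series)
        p = outdir / "analysis.csv"
        lagged.to_csv(p, index=False)
        excl.to_csv(outdir / "exclusions.csv", index=False)
        paths["analysis"] = str(p)
        paths["exclusions"] = str(outdir / "exclusions.csv")
        logger.info("preprocess: %d persons excluded, %d analysis rows", len(excl), len(lagged))
        return lagged

    @_stage("design")
    def stage_design(lagged):
        reference = config["reference_group"]
        return GroupDesign.from_labels(lagged["group"], reference,
                                       pooled=bool(config.get("pooled_patients", False)))

    @_stage("fit-freq")
    def stage_freq(lagged, design):
        opts = dict(config.get("freq", {}))
        fit = fit_mels(lagged, design, seed=master_seed, **opts)
        meta = fit.metadata()
        (outdir / "freq_meta.json").write_text(json.dumps(meta, indent=2))
        wald_table(fit).to_csv(outdir / "freq_table.csv", index=False)
        paths["freq_table"] = str(outdir / "freq_table.csv")
        logger.info("fit-freq: loglik=%.3f converged=%s", fit.loglik, fit.converged)
        return fit

    @_stage("fit-bayes")
    def stage_bayes(lagged, design):
        opts = dict(config.get("bayes", {}))
        opts.setdefault("seed", master_seed)
        cfg = bayes_mod.McmcConfig(**opts)
        draws = bayes_mod.run_mcmc(lagged, design, config=cfg)
        draws.to_csv(outdir / "draws.csv")
        report = bayes_mod.convergence_report(draws)
        (outdir / "convergence.json").write_text(json.dumps(report.to_dict(), indent=2))
        pm = bayes_mod.posterior_person_means(draws)
        pm.to_csv(outdir / "person_means.csv", index=False)
        summary = bayes_mod.group_contrast_summary(draws)
        summary.to_csv(outdir / "bayes_contrasts.csv", index=False)
        paths.update(draws=str(outdir / "draws.csv"),
                     convergence=str(outdir / "convergence.json"),
                     person_means=str(outdir / "person_means.csv"),
                     bayes_contrasts=str(outdir / "bayes_contrasts.csv"))
        logger.info("fit-bayes: worst PSRF %.4f (%s)", report.worst, report.worst_parameter)
        return draws, report, pm, summary

    @_stage("report")
    def stage_report(fit, summary, person_means, report):
        table = render_tables(fit, summary)
        table.to_csv(outdir / "report_table.csv", index=False)
        text = format_table_text(table)
        (outdir / "report_table.txt").write_text(text + "\n")
        dens = render_density_plots(person_means, outdir)
        paths["report_table"] = str(outdir / "report_table.csv")
        for comp, info in dens.items():
            paths[f"density_{comp}"] = info["path"]
        checks = {k: _sha256(Path(v)) for k, v in paths.items() if Path(v).suffix == ".csv"}
        meta = {
            "seed": master_seed,
            "version": affectdyn.__version__,
            "worst_psrf": report.worst,
            "checksums": checks,
        }
        (outdir / "report_meta.json").write_text(json.dumps(meta, indent=2))
        return ReportBundle(table=table, table_text=text, density_data=dens, paths=dict(paths), metadata=meta)

    frame = stage_simulate()
    lagged = stage_preprocess(frame)
    design = stage_design(lagged)
    fit = stage_freq(lagged, design)
    draws, conv, person_means, summary = stage_bayes(lagged, design)
    return stage_report(fit, summary, person_means, conv)


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)
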