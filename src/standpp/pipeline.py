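"""End-to-end analysis pipeline and reporting.

Chains the stages — synthetic generation (or census loading), stand
summaries, spatial statistics, Monte Carlo envelopes, and variable
importance — into a run directory of CSV artifacts plus a machine-
readable manifest (inputs, seed, package versions, output checksums).
Rerunning the same configuration reproduces the outputs byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .census import (Census, CovariateRaster, PlotWindow, read_ascii_raster,
                     read_stem_table, validate_census, write_ascii_raster,
                     write_stem_table)
from .errors import ConfigurationError, StandppError
from .habitat import build_feature_table, ensemble_importance
from .montecarlo import NullSpec, envelope_test
from .pointpattern import LagSpec, MarkedPattern
from .structure import AllometryTable, species_summary
from .synthetic import SyntheticTruth, default_truth, generate_synthetic_census

__all__ = ["RunConfig", "run_pipeline", "make_report"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one pipeline run (see ``RunConfig.from_toml``)."""

    seed: int = 0
    outdir: str = "standpp_run"
    census_path: str | None = None       # read a census instead of simulating
    allometry_path: str | None = None    # CSV; generic fallback when absent
    # synthetic-stand block (used when census_path is None)
    n_species: int = 5
    total_stems: int = 4000
    window_width: float = 500.0
    window_height: float = 700.0
    # spatial-analysis block
    top_k_species: int = 3
    focal_species: str | None = None     # defaults to the most abundant
    r_max_pcf: float = 50.0
    r_max_mark: float = 150.0
    r_step: float = 1.0
    bandwidth: float = 5.0
    nsim: int = 199
    rank: int = 5
    # importance block
    radius: float = 10.0
    cell_size: float = 20.0
    n_iter: int = 100
    subsample: float = 0.632
    alpha: float = 0.05
    min_node: int = 20
    threads: int = 1

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        flat: dict = {}
        for section in doc.values():
            if isinstance(section, dict):
                flat.update(section)
        unknown = set(flat) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def lag_spec(self, statistic: str) -> LagSpec:
        rmax = self.r_max_pcf if statistic == "g" else self.r_max_mark
        r = tuple(np.arange(self.r_step, rmax + 1e-9, self.r_step))
        return LagSpec(r_values=r, h=self.bandwidth)

    def validate(self, window: PlotWindow) -> None:
        half = min(window.width, window.height) / 2.0
        for rmax in (self.r_max_pcf, self.r_max_mark):
            if rmax > half:
                raise ConfigurationError(
                    f"max lag {rmax} m exceeds half the shorter window side "
                    f"({half} m); reduce r_max or enlarge the window")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


ALL_STAGES = ("census", "summaries", "envelopes", "importance")


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = ALL_STAGES) -> Path:
    """Execute the requested stages; returns the run directory.

    Emits: census CSV + mosaic grid + truth JSON (synthetic runs), species
    summaries, estimator curves with envelopes, importance tables, and
    ``manifest.json`` recording the seed, versions and a SHA-256 checksum
    of every artifact.  The census stage always runs (later stages need
    its output); other stages run only when requested.
    """
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigurationError(f"unknown pipeline stages: {sorted(unknown)}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # --- stage: census -------------------------------------------------
        stage = "census"
        if config.census_path:
            census = read_stem_table(config.census_path,
                                     window=PlotWindow(config.window_width,
                                                       config.window_height))
            mosaic = None
        else:
            truth = default_truth(seed=config.seed, n_species=config.n_species,
                                  total_stems=config.total_stems,
                                  window=PlotWindow(config.window_width,
                                                    config.window_height))
            census, mosaic = generate_synthetic_census(truth)
            truth.to_json(out / "truth.json")
            write_stem_table(census, out / "census.csv")
            write_ascii_raster(mosaic, out / "landuse.asc")
        config.validate(census.window)
        report = validate_census(census)
        if not report.ok:
            raise StandppError(f"census failed validation:\n{report}")

        # --- stage: summaries ----------------------------------------------
        stage = "summaries"
        allometry = (AllometryTable.from_csv(config.allometry_path)
                     if config.allometry_path else AllometryTable.generic())
        summary = species_summary(census, allometry)
        if "summaries" in stages:
            summary.to_csv(out / "species_summary.csv", index=False,
                           float_format="%.10g")

        # --- stage: spatial statistics + envelopes -------------------------
        stage = "envelopes"
        live = summary[summary.species_code != "TOTAL"]
        ranked = live.sort_values("n_individuals", ascending=False)
        top = list(ranked["species_code"].head(config.top_k_species))
        focal_code = config.focal_species or (top[0] if top else None)
        seed_root = np.random.SeedSequence(config.seed)
        g_ss, k_ss, i_ss = seed_root.spawn(3)
        env_species = top if "envelopes" in stages else []
        for idx, code in enumerate(env_species):
            pat = MarkedPattern.from_census(census, species=code)
            if pat.n < 2:
                log.info("skipping %s: fewer than 2 points", code)
                continue
            env_g = envelope_test(
                pat, "g", config.lag_spec("g"),
                NullSpec("csr", config.nsim, config.rank,
                         seed=int(g_ss.generate_state(1)[0] >> 33) + idx),
                threads=config.threads)
            env_g.to_csv(out / f"envelope_g_{code}.csv")
            env_k = envelope_test(
                pat, "kmm", config.lag_spec("kmm"),
                NullSpec("shuffle_marks_all", config.nsim, config.rank,
                         seed=int(k_ss.generate_state(1)[0] >> 33) + idx),
                threads=config.threads)
            env_k.to_csv(out / f"envelope_kmm_{code}.csv")
        if focal_code is not None and env_species:
            focal = MarkedPattern.from_census(census, species=focal_code)
            for idx, code in enumerate(env_species):
                if code == focal_code:
                    continue
                other = MarkedPattern.from_census(census, species=code)
                if focal.n < 2 or other.n < 2:
                    continue
                env_i = envelope_test(
                    focal, "I", config.lag_spec("I"),
                    NullSpec("shuffle_marks_nonfocal", config.nsim, config.rank,
                             seed=int(i_ss.generate_state(1)[0] >> 33) + idx),
                    other=other, threads=config.threads)
                env_i.to_csv(out / f"envelope_I_{focal_code}_vs_{code}.csv")

        # --- stage: importance ---------------------------------------------
        stage = "importance"
        rasters = {"landuse": mosaic} if mosaic is not None else {}
        imp_species = top[:1] if "importance" in stages else []
        for code in imp_species:
            features = build_feature_table(census, code, rasters,
                                           radius=config.radius,
                                           cell_size=config.cell_size)
            features.to_csv(out / f"features_{code}.csv", index=False,
                            float_format="%.10g")
            X = features.drop(columns=["abundance", "dbh", "border"]).dropna()
            if len(X) >= 2 * config.min_node and len(X.columns) >= 2:
                y = features.loc[X.index, "abundance"]
                rng = np.random.default_rng(np.random.SeedSequence(
                    (config.seed, 0x1F0)))
                imp = ensemble_importance(
                    X.reset_index(drop=True), y.to_numpy(),
                    n_iter=config.n_iter, subsample=config.subsample,
                    alpha=config.alpha, min_node=config.min_node, rng=rng)
                imp.to_csv(out / f"importance_abundance_{code}.csv")

        # --- stage: manifest -----------------------------------------------
        stage = "manifest"
        artifacts = sorted(p for p in out.iterdir()
                           if p.is_file() and p.name != "manifest.json")
        manifest = {
            "seed": config.seed,
            "config": {k: getattr(config, k)
                       for k in sorted(RunConfig.__dataclass_fields__)},
            "versions": {"standpp": __version__,
                         "numpy": np.__version__, "pandas": pd.__version__,
                         "python": ".".join(map(str, sys.version_info[:3]))},
            "outputs": {p.name: _sha256(p) for p in artifacts},
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8")
    except Exception:
        log.error("pipeline failed in stage %r", stage)
        raise
    return out


def make_report(rundir) -> Path:
    """Render a completed run into ``report.md`` plus figure files.

    Produces the per-species summary table, one envelope plot per
    statistic/species artifact, and importance bar charts.  An incomplete
    run raises, listing the missing artifacts.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rundir = Path(rundir)
    missing = [n for n in ("manifest.json", "species_summary.csv")
               if not (rundir / n).exists()]
    if missing:
        raise StandppError(f"incomplete run, missing artifacts: {missing}")
    figdir = rundir / "figures"
    figdir.mkdir(exist_ok=True)
    lines = ["# Stand analysis report", ""]
    manifest = json.loads((rundir / "manifest.json").read_text())
    lines += [f"Seed: {manifest['seed']}; standpp {manifest['versions']['standpp']}", ""]

    summary = pd.read_csv(rundir / "species_summary.csv")
    lines += ["## Species summary", "", "```",
              summary.to_string(index=False, float_format="%.3f"), "```", ""]
    env_files = sorted(rundir.glob("envelope_*.csv"))
    if env_files:
        lines += ["## Envelope tests", ""]
    for path in env_files:
        env = pd.read_csv(path)
        name = path.stem
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.fill_between(env["r"], env["lower"], env["upper"],
                        color="0.8", label="null envelope")
        ax.plot(env["r"], env["observed"], color="tab:blue", label="observed")
        stat = name.split("_")[1]
        ref = 1.0 if stat in ("g", "kmm") else 0.0
        ax.axhline(ref, color="k", ls="--", lw=0.8)
        ax.set_xlabel("r (m)")
        ax.set_ylabel(stat)
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(figdir / f"{name}.png", dpi=120)
        plt.close(fig)
        n_above = int((env["call"] == "above").sum())
        n_below = int((env["call"] == "below").sum())
        lines += [f"![{name}](figures/{name}.png)",
                  f"`{name}`: {n_above} lag(s) above, {n_below} below the "
                  f"envelope of {len(env)} lags.", ""]
    for path in sorted(rundir.glob("importance_*.csv")):
        imp = pd.read_csv(path).sort_values("importance")
        name = path.stem
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.barh(imp["predictor"], imp["importance"], xerr=imp["se"],
                color="tab:green")
        ax.set_xlabel("mean decrease in prediction accuracy")
        fig.tight_layout()
        fig.savefig(figdir / f"{name}.png", dpi=120)
        plt.close(fig)
        lines += [f"## Variable importance: {name}", "",
                  f"![{name}](figures/{name}.png)", "", "```",
                  imp.sort_values("importance", ascending=False)
                     .to_string(index=False, float_format="%.4f"), "```", ""]
    report = rundir / "report.md"
    report.write_text("\n".join(lines), encoding="utf-8")
    return report
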