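"""Pipeline orchestration: conditioning -> mdALFF -> seed selection -> dFC ->
statistics -> report, with a reproducibility manifest.

Each stage reads and writes files under a run directory, so stages can be
re-run independently from the CLI.  The manifest records the configuration
snapshot, the RNG seed, content hashes of every output, per-stage row counts
and wall timestamps; a completed run with an unchanged configuration is a
no-op on re-entry.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import __version__
from .atlas import filter_defined_networks, write_atlas
from .cohort import (CLINICAL_SCORES, CohortDataset, load_cohort,
                     write_phenotypes, write_series)
from .conditioning import condition_series
from .metrics import (WindowSpec, compute_dfc_cohort, compute_mdalff_cohort)
from .simulate import (AmplitudeEffect, CorrelationTarget, DfcEffect,
                       SimulationSpec, simulate_cohort)
from .stats import (contrast_table, correlation_grid, fit_group_glm, nbs_test)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "tr": 2.5,
    "conditioning": {
        "trim_volumes": 10,
        "bandpass": [0.01, 0.1],
        "motion_limits": {"translation_mm": 2.0, "rotation_deg": 2.0, "mean_fd_mm": 0.5},
    },
    "alff_band": [0.01, 0.08],
    "window": {"length_tr": 50, "step_tr": 10},
    "stats": {"alpha_primary": 0.005, "alpha_marginal": 0.01, "fdr_q": 0.05},
    "nbs": {"n_perm": 1000, "alpha": 0.05, "primary_p": 0.005},
    "seeds": None,          # explicit dFC seed ROI list; None = select from contrasts
    "simulate": {},         # SimulationSpec overrides; presence triggers simulation
    "inputs": None,         # {"atlas": ..., "phenotypes": ..., "series_dir": ...}
}


def load_config(path_or_dict) -> dict:
    """Merge a YAML config file (or dict) over the defaults."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _spec_from_config(cfg: dict) -> SimulationSpec:
    over = dict(cfg.get("simulate") or {})
    for key, cls in (("amplitude_effects", AmplitudeEffect),
                     ("dfc_effects", DfcEffect),
                     ("correlation_targets", CorrelationTarget)):
        if key in over and over[key] is not None:
            over[key] = tuple(cls(*item) if not isinstance(item, cls) else item
                              for item in over[key])
    over.setdefault("tr", cfg["tr"])
    return SimulationSpec(seed=cfg["seed"], **over)


def write_cohort(dataset: CohortDataset, out_dir: Path) -> None:
    """Emit atlas TSV, phenotype CSV and one series file per subject."""
    out_dir.mkdir(parents=True, exist_ok=True)
    write_atlas(dataset.atlas, out_dir / "atlas.tsv")
    write_phenotypes(dataset.phenotypes, out_dir / "phenotypes.csv")
    series_dir = out_dir / "series"
    series_dir.mkdir(exist_ok=True)
    for sid, series in dataset.series.items():
        write_series(series, series_dir / f"{sid}.tsv")


class PipelineRun:
    """Stateful helper executing the stages of one run directory."""

    def __init__(self, cfg: dict, out_dir: Path):
        self.cfg = cfg
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.window = WindowSpec(cfg["window"]["length_tr"], cfg["window"]["step_tr"])
        self.manifest: dict = {
            "version": __version__,
            "seed": cfg["seed"],
            "config": cfg,
            "config_hash": config_hash(cfg),
            "started": datetime.datetime.now().isoformat(timespec="seconds"),
            "outputs": {},
            "counts": {},
        }
        self.dataset: CohortDataset | None = None
        self.conditioned: CohortDataset | None = None

    # -- stages ------------------------------------------------------------
    def stage_input(self) -> None:
        cfg = self.cfg
        if cfg.get("inputs"):
            inp = cfg["inputs"]
            self.dataset = load_cohort(inp["atlas"], inp["phenotypes"],
                                       inp["series_dir"], tr=cfg["tr"])
            logger.info("loaded cohort: %d subjects", self.dataset.n_subjects)
        else:
            spec = _spec_from_config(cfg)
            self.dataset = simulate_cohort(spec, rng=cfg["seed"])
            write_cohort(self.dataset, self.out / "cohort")
            logger.info("simulated cohort: %d subjects (%s)",
                        self.dataset.n_subjects, self.dataset.group_sizes())
        self.manifest["counts"]["subjects"] = self.dataset.n_subjects
        self.manifest["counts"]["atlas_rois"] = self.dataset.atlas.n_roi

    def stage_condition(self) -> None:
        cfg = self.cfg["conditioning"]
        assert self.dataset is not None
        atlas = filter_defined_networks(self.dataset.atlas)
        series = {
            sid: condition_series(s, trim_volumes=cfg["trim_volumes"],
                                  band=tuple(cfg["bandpass"]))
            for sid, s in self.dataset.series.items()}
        self.conditioned = CohortDataset(
            atlas=atlas, phenotypes=self.dataset.phenotypes, series=series)
        first = next(iter(series.values()))
        self.manifest["counts"]["analysis_rois"] = atlas.n_roi
        self.manifest["counts"]["timepoints"] = first.n_timepoints
        logger.info("conditioned %d subjects; %d analysis ROIs, %d timepoints",
                    len(series), atlas.n_roi, first.n_timepoints)

    def stage_mdalff(self) -> pd.DataFrame:
        assert self.conditioned is not None
        mdalff = compute_mdalff_cohort(
            self.conditioned, spec=self.window, band=tuple(self.cfg["alff_band"]))
        self._save_table(mdalff, "mdalff.tsv")
        self.manifest["counts"]["windows"] = self.window.n_windows(
            next(iter(self.conditioned.series.values())).n_timepoints)
        return mdalff

    def stage_mdalff_stats(self, mdalff: pd.DataFrame) -> pd.DataFrame:
        assert self.conditioned is not None
        parts = [contrast_table(mdalff, self.conditioned.phenotypes,
                                self.conditioned.atlas, col)
                 for col in ("mdalff_mean", "mdalff_var")]
        contrasts = pd.concat(parts, ignore_index=True)
        self._save_table(contrasts, "contrasts_mdalff.tsv")
        return contrasts

    def select_seeds(self, contrasts: pd.DataFrame) -> list[int]:
        """ROIs whose mean or variance contrast crosses the primary threshold,
        unless the config names an explicit seed list."""
        if self.cfg.get("seeds"):
            return [int(s) for s in self.cfg["seeds"]]
        alpha = self.cfg["stats"]["alpha_primary"]
        hits = contrasts.loc[contrasts["p_raw"] < alpha, "roi_id"]
        return sorted(hits.unique().tolist())

    def stage_dfc(self, seeds: list[int]) -> pd.DataFrame | None:
        assert self.conditioned is not None
        if not seeds:
            logger.warning("no seed ROI crossed the primary threshold; skipping dFC")
            return None
        dfc = compute_dfc_cohort(self.conditioned, seeds, spec=self.window)
        self._save_table(dfc, "dfc.tsv")
        self.manifest["counts"]["dfc_seeds"] = len(seeds)
        return dfc

    def stage_dfc_stats(self, dfc: pd.DataFrame | None) -> pd.DataFrame | None:
        if dfc is None:
            return None
        assert self.conditioned is not None
        pheno = self.conditioned.phenotypes
        parts = []
        edges: list[tuple[int, int]] = []
        edge_cols = {}
        for col in ("dfc_mean", "dfc_var"):
            wide = dfc.pivot_table(index="subject_id", columns=["seed_roi", "target_roi"],
                                   values=col).loc[pheno["subject_id"]]
            res = fit_group_glm(wide.to_numpy(), pheno)
            res.insert(0, "seed_roi", [c[0] for c in wide.columns])
            res.insert(1, "target_roi", [c[1] for c in wide.columns])
            res.insert(2, "metric", col)
            from .stats import fdr_correct
            res["q_wholebrain"] = fdr_correct(res["p_raw"].to_numpy())
            parts.append(res)
            edge_cols[col] = wide
        contrasts = pd.concat(parts, ignore_index=True)
        self._save_table(contrasts, "contrasts_dfc.tsv")

        # NBS on the dFC-mean edge family
        wide = edge_cols["dfc_mean"]
        edges = [(int(a), int(b)) for a, b in wide.columns]
        nbs_cfg = self.cfg["nbs"]
        result = nbs_test(wide.to_numpy(), edges, pheno,
                          n_perm=nbs_cfg["n_perm"], primary_p=nbs_cfg["primary_p"],
                          rng=self.cfg["seed"])
        payload = {
            "components": [[[int(u), int(v)] for u, v in comp]
                           for comp in result.components],
            "component_sizes": [int(s) for s in result.component_sizes],
            "p_fwe": [float(p) for p in result.p_fwe],
            "n_permutations": result.n_permutations,
            "primary_threshold": result.primary_threshold,
            "alpha": nbs_cfg["alpha"],
            "seed": self.cfg["seed"],
        }
        path = self.out / "nbs.json"
        path.write_text(json.dumps(payload, indent=1))
        self._register(path)
        return contrasts

    def stage_correlations(self, mdalff: pd.DataFrame,
                           contrasts: pd.DataFrame) -> pd.DataFrame:
        assert self.conditioned is not None
        alpha = self.cfg["stats"]["alpha_primary"]
        rois = sorted(contrasts.loc[contrasts["p_raw"] < alpha, "roi_id"].unique())
        if not rois:
            rois = sorted(contrasts.nsmallest(3, "p_raw")["roi_id"].unique())
        grid = correlation_grid(mdalff, self.conditioned.phenotypes,
                                [int(r) for r in rois], CLINICAL_SCORES)
        self._save_table(grid, "correlations.tsv")
        return grid

    def stage_report(self, contrasts: pd.DataFrame | None,
                     grid: pd.DataFrame | None) -> Path:
        assert self.dataset is not None
        path = write_report(self.out, self.dataset.phenotypes, contrasts, grid,
                            alpha=self.cfg["stats"]["alpha_primary"],
                            alpha_marginal=self.cfg["stats"]["alpha_marginal"],
                            atlas=self.conditioned.atlas if self.conditioned else None)
        self._register(path)
        return path

    # -- bookkeeping -------------------------------------------------------
    def _save_table(self, table: pd.DataFrame, name: str) -> None:
        path = self.out / name
        table.to_csv(path, sep="\t", index=False, float_format="%.10g")
        self._register(path)
        self.manifest["counts"][name] = len(table)

    def _register(self, path: Path) -> None:
        self.manifest["outputs"][path.name] = _file_hash(path)

    def finish(self) -> dict:
        self.manifest["finished"] = datetime.datetime.now().isoformat(timespec="seconds")
        (self.out / "manifest.json").write_text(json.dumps(self.manifest, indent=1))
        return self.manifest


def run_pipeline(config, out_dir) -> dict:
    """Execute every stage and return the manifest.

    ``config`` is a YAML path or dict; missing keys fall back to defaults.
    Rerunning a completed directory with an unchanged config returns the
    existing manifest without recomputation.
    """
    cfg = load_config(config)
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.json"
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == config_hash(cfg) and old.get("finished"):
            logger.info("run directory up to date (config hash %s); skipping",
                        old["config_hash"])
            return old

    run = PipelineRun(cfg, out_dir)
    run.stage_input()
    run.stage_condition()
    mdalff = run.stage_mdalff()
    contrasts = run.stage_mdalff_stats(mdalff)
    seeds = run.select_seeds(contrasts)
    dfc = run.stage_dfc(seeds)
    run.stage_dfc_stats(dfc)
    grid = run.stage_correlations(mdalff, contrasts)
    run.stage_report(contrasts, grid)
    return run.finish()


def demographic_comparison(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Between-group demographic/clinical table: Welch t for continuous
    columns, chi-square for sex."""
    scd = phenotypes[phenotypes["group"] == "SCD"]
    nc = phenotypes[phenotypes["group"] == "NC"]
    rows = []
    for col in ["age", "education", "mean_fd"] + [
            s for s in CLINICAL_SCORES if s in phenotypes.columns]:
        a, b = scd[col].dropna(), nc[col].dropna()
        t, p = sps.ttest_ind(a, b, equal_var=False)
        rows.append((col, f"{a.mean():.2f} ± {a.std():.2f}",
                     f"{b.mean():.2f} ± {b.std():.2f}", p))
    table = pd.crosstab(phenotypes["group"], phenotypes["sex"])
    chi2, p_sex = sps.chi2_contingency(table)[:2]
    n_f_scd = int((scd["sex"] == "female").sum())
    n_f_nc = int((nc["sex"] == "female").sum())
    rows.insert(1, ("sex, female",
                    f"{n_f_scd} ({100 * n_f_scd / len(scd):.1f}%)",
                    f"{n_f_nc} ({100 * n_f_nc / len(nc):.1f}%)", p_sex))
    return pd.DataFrame(rows, columns=["variable", "SCD", "NC", "p_value"])


def write_report(out_dir: Path, phenotypes: pd.DataFrame,
                 contrasts: pd.DataFrame | None, grid: pd.DataFrame | None,
                 alpha: float = 0.005, alpha_marginal: float = 0.01,
                 atlas=None) -> Path:
    """Markdown summary: demographics, significant/marginal ROI lists,
    correlation grid flags."""
    out_dir = Path(out_dir)
    lines = ["# Dynamic connectivity run report", ""]

    demo = demographic_comparison(phenotypes)
    demo.to_csv(out_dir / "demographics.tsv", sep="\t", index=False)
    lines += ["## Group comparison", "",
              demo.to_string(index=False), ""]

    if contrasts is not None and len(contrasts):
        sig = contrasts[contrasts["p_raw"] < alpha]
        marg = contrasts[(contrasts["p_raw"] >= alpha)
                         & (contrasts["p_raw"] < alpha_marginal)]
        lines.append(f"## Group contrasts (p < {alpha} significant, "
                     f"< {alpha_marginal} marginal)")
        lines.append("")
        if len(sig):
            cols = [c for c in ("roi_id", "metric", "network", "beta_group",
                                "t_stat", "p_raw", "q_wholebrain", "q_network")
                    if c in sig.columns]
            lines += [sig[cols].to_string(index=False), ""]
        else:
            lines += ["no significant ROIs", ""]
        if len(marg):
            lines += [f"{len(marg)} marginal ROI contrast(s).", ""]
    else:
        lines += ["## Group contrasts", "", "no significant ROIs", ""]

    if grid is not None and len(grid):
        hits = grid[grid["q_fdr"] < 0.05]
        lines.append("## Clinical partial correlations (FDR q < 0.05)")
        lines.append("")
        if len(hits):
            lines += [hits[["roi_id", "metric", "score", "r_all", "q_fdr"]]
                      .to_string(index=False), ""]
        else:
            lines += ["no significant correlations", ""]

    path = out_dir / "report.md"
    path.write_text("\n".join(lines))
    return path
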