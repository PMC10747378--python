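"""End-to-end orchestration: simulate/load → pretreat → aquagrams →
significance tables → PLS calibration, with a manifest of every artifact.

Every figure written by the pipeline has a machine-readable CSV twin, and
the whole bundle is a deterministic function of the configuration and
seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aquagram import compute_aquagram, export_aquagram
from .chemometrics import correlation_spectrum, grouped_cv, important_bands
from .group_stats import wamac_significance
from .preprocess import SgConfig, difference_spectra, msc_fit_transform, sg_derivative
from .spectra import SpectraSet, load_spectra, select_wavelength_range, subset, \
    average_spectra, write_spectra
from .synthetic import GeneratorConfig, generate_experiment


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved settings for a full pipeline run."""

    input_csv: str | None = None        # if None, simulate
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    sg: SgConfig = field(default_factory=SgConfig)
    window: tuple[float, float] = (1300.0, 1600.0)
    aquagram_by: tuple[str, ...] = ("treatment",)
    aquagram_split: tuple[str, ...] = ("line_label", "leaf_index")
    significance_leaf: int = 3
    max_factors: int = 10
    baseline_day: int = 3
    seed: int = 0
    outdir: str = "aqualeaf_out"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        gen = GeneratorConfig(**raw.pop("generator", {})) if "generator" in raw \
            else GeneratorConfig()
        sg = SgConfig(**raw.pop("sg", {})) if "sg" in raw else SgConfig()
        if "window" in raw:
            raw["window"] = tuple(raw["window"])
        cfg = cls(generator=gen, sg=sg, **raw)
        if "seed" in overrides or "seed" in raw:
            cfg = replace(cfg, generator=replace(gen, seed=cfg.seed))
        return cfg

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("outdir")  # output location is not part of the analysis
        d["generator"]["wavelengths"] = [
            float(w) for w in np.asarray(self.generator.wavelengths)
        ]
        d["generator"]["bands"] = [
            dataclasses.asdict(b) for b in self.generator.bands
        ]
        return d


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Human-readable issues; the config is runnable iff the list is empty."""
    issues: list[str] = []
    if cfg.input_csv is not None and not Path(cfg.input_csv).exists():
        issues.append(f"input file {cfg.input_csv} does not exist")
    issues.extend(cfg.generator.validate())
    lo, hi = cfg.window
    if not lo < hi:
        issues.append(f"window [{lo}, {hi}] is empty")
    else:
        wl = np.asarray(cfg.generator.wavelengths)
        if cfg.input_csv is None and (lo > wl[-1] or hi < wl[0]):
            issues.append(f"window [{lo}, {hi}] lies outside the grid")
    if cfg.max_factors < 1:
        issues.append("max_factors must be >= 1")
    if cfg.significance_leaf not in (cfg.generator.leaves or (cfg.significance_leaf,)):
        issues.append(
            f"significance_leaf {cfg.significance_leaf} not among leaves "
            f"{cfg.generator.leaves}"
        )
    return issues


def _write_set_csv(s: SpectraSet, path: Path) -> Path:
    write_spectra(s, path)
    return path


def run(cfg: PipelineConfig, make_figures: bool = True) -> dict:
    """Execute the full pipeline and return the manifest (also written to
    ``outdir/manifest.json``).

    Stages: simulate/load → group-mean derivative and difference spectra →
    MSC + aquagrams per (line, leaf) → per-WAMAC significance tables →
    PLS drought-day calibration per line with grouped CV.
    """
    issues = validate_config(cfg)
    if issues:
        raise ValueError("invalid pipeline config: " + "; ".join(issues))
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_jsonable(),
        "outputs": [],
        "shapes": {},
        "errors": [],
    }

    def record(path: Path) -> None:
        manifest["outputs"].append(str(path.relative_to(out)))

    stage = "input"
    try:
        # ---- input ---------------------------------------------------
        if cfg.input_csv is None:
            gen_cfg = replace(cfg.generator, seed=cfg.seed)
            sset, truth = generate_experiment(gen_cfg)
            record(_write_set_csv(sset, out / "spectra.csv"))
            truth.records.to_csv(
                out / "ground_truth.csv", index=False, float_format="%.17g"
            )
            record(out / "ground_truth.csv")
        else:
            sset = load_spectra(cfg.input_csv)
        manifest["shapes"]["spectra"] = [sset.n_spectra, sset.n_bands]
        lines = list(pd.unique(sset.meta["line_label"]))

        # ---- derivative path: group means + difference spectra -------
        stage = "derivative"
        deriv = sg_derivative(sset, cfg.sg)
        means = average_spectra(
            deriv, ["line_label", "treatment", "stage_tag", "day"]
        )
        record(_write_set_csv(means, out / "derivative_group_means.csv"))
        stress_deriv = subset(deriv, "treatment == 'stress'")
        diffs = difference_spectra(
            stress_deriv, cfg.baseline_day, field="day", within=["line_label"]
        )
        record(_write_set_csv(diffs, out / "difference_spectra.csv"))
        manifest["shapes"]["difference_spectra"] = [diffs.n_spectra, diffs.n_bands]

        # ---- aquagram path: MSC then z-scores per line × leaf --------
        stage = "aquagram"
        for line in lines:
            for leaf in sorted(pd.unique(sset.meta["leaf_index"])):
                sub = subset(
                    sset,
                    f"line_label == {line!r} and leaf_index == {leaf}",
                )
                corrected, _ = msc_fit_transform(sub)
                res = compute_aquagram(corrected, by=list(cfg.aquagram_by))
                tag = f"{line}_leaf{leaf}"
                chart = out / f"aquagram_{tag}.png" if make_figures else None
                for p in export_aquagram(res, out / f"aquagram_{tag}.csv", chart):
                    record(p)

        # ---- significance tables -------------------------------------
        stage = "significance"
        for line in lines:
            sub = subset(
                sset,
                f"line_label == {line!r} and leaf_index == {cfg.significance_leaf}",
            )
            corrected, _ = msc_fit_transform(sub)
            res = compute_aquagram(corrected, by=["treatment"])
            table = wamac_significance(res, group_field="treatment")
            path = out / f"significance_{line}.csv"
            table.to_csv(path, index=False, float_format="%.17g")
            record(path)

        # ---- PLS drought-day calibration per line --------------------
        stage = "pls"
        lo, hi = cfg.window
        for line in lines:
            stress = subset(
                sset, f"line_label == {line!r} and treatment == 'stress'"
            )
            d = select_wavelength_range(sg_derivative(stress, cfg.sg), lo, hi)
            y = d.meta["day"].to_numpy(dtype=float)
            groups = (
                d.meta["plant_id"].astype(str)
                + "|L" + d.meta["leaf_index"].astype(str)
                + "|D" + d.meta["day"].astype(str)
            ).to_numpy()
            report = grouped_cv(
                d.absorbance, y, groups, max_factors=cfg.max_factors,
                wavelengths=d.wavelengths,
            )
            corr = correlation_spectrum(d.absorbance, y)
            top = important_bands(report.model, 5, d.wavelengths)
            rep = {
                "line": str(line),
                "n_spectra": int(d.n_spectra),
                "n_bands": int(d.n_bands),
                "window_nm": [lo, hi],
                "n_factors": int(report.n_factors),
                "secv": report.secv,
                "sec": report.sec,
                "r2cv": report.r2cv,
                "r2cal": report.r2cal,
                "r2cv_press": report.r2cv_press,
                "secv_curve": [float(v) for v in report.secv_curve],
                "top_bands": [[w, c] for w, c in top],
            }
            path = out / f"pls_report_{line}.json"
            path.write_text(json.dumps(rep, indent=2, sort_keys=True))
            record(path)
            vec = pd.DataFrame(
                {
                    "wavelength_nm": d.wavelengths,
                    "regression_coefficient": report.model.regression_vector,
                    "correlation_r": corr,
                }
            )
            vpath = out / f"pls_vectors_{line}.csv"
            vec.to_csv(vpath, index=False, float_format="%.17g")
            record(vpath)
            if make_figures:
                import matplotlib

                matplotlib.use("Agg")
                import matplotlib.pyplot as plt

                fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
                axes[0].plot(d.wavelengths, report.model.regression_vector)
                axes[0].set_ylabel("regression coefficient")
                axes[1].plot(d.wavelengths, corr)
                axes[1].set_ylabel("correlation r")
                axes[1].set_xlabel("wavelength (nm)")
                fig.suptitle(f"PLS drought-day model — {line}")
                fpath = out / f"pls_vectors_{line}.png"
                fig.savefig(fpath, dpi=120)
                plt.close(fig)
                record(fpath)
    except Exception as exc:
        manifest["errors"].append({"stage": stage, "error": str(exc)})
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["outputs"].append("manifest.json")
    return manifest
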