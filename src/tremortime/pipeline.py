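"""End-to-end orchestration of the synthetic experiments and model studies.

`run_experiment` drives one modality through the whole analysis chain:
generate trials -> RT filtering -> psychometric fits per condition ->
repeated-measures ANOVAs and linear contrasts on BP/CV/RT ->
direction-bin control -> per-subject CV slopes -> (optionally) DDM fits
per frequency and parameter-slope/behaviour-slope correlations.  All
artefacts (CSV tables, a stats JSON, a run manifest with config snapshot,
seeds and file digests) are written to an output directory; a stage
failure aborts with the stage name attached while earlier outputs are
retained.

`run_scaling_study` reproduces the three-level parameter-scaling
simulation for drift, threshold and alpha and checks the three qualitative
signatures (lower drift -> higher CV; lower threshold -> higher CV with
uniformly faster RTs; lower alpha -> higher CV).  Signature failures are
reported as findings in the summary, never raised.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from . import ddm_fit, levy_ddm, psychometrics, stats_analysis, synthetic_data

__all__ = ["RunManifest", "run_experiment", "run_scaling_study", "experiment_stats"]


@dataclass
class RunManifest:
    """Traceability record for one pipeline run."""

    config: dict
    seed: int
    package_version: str
    outputs: dict[str, str] = field(default_factory=dict)  # filename -> sha256
    started: float = field(default_factory=time.time)
    finished: float | None = None

    def record(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[path.name] = digest

    def write(self, path: Path) -> None:
        self.finished = time.time()
        path.write_text(json.dumps(asdict(self), indent=2, default=str))


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:  # noqa: BLE001 - re-raise with stage context
                raise StageError(f"stage {name!r} failed: {err}") from err

        return wrapped

    return deco


def experiment_stats(
    fits_full: pd.DataFrame,
    fits_by_freq: pd.DataFrame,
    trials: pd.DataFrame,
) -> dict[str, Any]:
    """Behavioural statistics bundle from fitted psychometric tables.

    Two-way rm-ANOVAs (amplitude x frequency) on CV and BP, mean RT ANOVA,
    the linear frequency contrast on CV (collapsed over amplitude),
    simple main effects of frequency within amplitude, and the
    direction-bin control on CV.
    """
    out: dict[str, Any] = {}
    for dv in ("cv", "bp_ms"):
        res = stats_analysis.rm_anova(
            fits_full, dv, "subject", ["amplitude_N", "frequency_Hz"]
        )
        out[f"anova_{dv}"] = [asdict(r) for r in res]

    rt_cells = (
        trials.groupby(["subject", "amplitude_N", "frequency_Hz"])["rt_ms"]
        .mean()
        .reset_index()
    )
    out["anova_rt"] = [
        asdict(r)
        for r in stats_analysis.rm_anova(
            rt_cells, "rt_ms", "subject", ["amplitude_N", "frequency_Hz"]
        )
    ]

    contrast = stats_analysis.linear_contrast(
        fits_by_freq, "cv", "subject", "frequency_Hz"
    )
    out["cv_frequency_linear_contrast"] = asdict(contrast)

    out["cv_simple_main_effects"] = stats_analysis.simple_main_effects(
        fits_full, "cv", "subject", "frequency_Hz", "amplitude_N"
    ).to_dict(orient="records")

    # direction-bin control: psychometric fit per subject x bin, one-way ANOVA
    binned = stats_analysis.direction_bins(trials)
    fits_bin = psychometrics.curves_by_condition(
        binned, group=("subject", "direction_bin")
    )
    ok = fits_bin["bp_ms"].notna()
    if fits_bin[ok].groupby("subject")["direction_bin"].nunique().eq(3).all():
        for dv in ("cv", "bp_ms"):
            res = stats_analysis.rm_anova_one_way(
                fits_bin[ok], dv, "subject", "direction_bin"
            )
            out[f"direction_control_{dv}"] = asdict(res)
    return out


def run_experiment(config: dict, outdir: str | Path | None = None) -> dict[str, Any]:
    """Run one synthetic experiment end to end; return the results bundle.

    ``config`` keys (all optional): ``modality`` ("auditory"/"visual"),
    ``seed``, ``n_subjects``, ``skip_ddm`` (default True; DDM fitting is
    the slow optional stage), ``observer`` (keyword overrides for
    :class:`~tremortime.synthetic_data.ObserverConfig`), ``ddm`` (kwargs
    for :func:`~tremortime.ddm_fit.fit_ddm_condition`).  When ``outdir``
    is given, trial/fit/slope CSVs, a stats JSON and a manifest are
    written there.
    """
    modality = config.get("modality", "auditory")
    seed = int(config.get("seed", 0))
    skip_ddm = bool(config.get("skip_ddm", True))

    manifest = RunManifest(config=dict(config), seed=seed, package_version=__version__)
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    def _generate():
        design = synthetic_data.DesignConfig(
            n_subjects=int(config.get("n_subjects", 24)), seed=seed
        )
        observer = synthetic_data.ObserverConfig(**config.get("observer", {}))
        return synthetic_data.generate_dataset(design, observer, modality=modality)

    trials = _stage("generate")(_generate)()
    kept, exclusions = _stage("filter_rts")(psychometrics.filter_rts)(trials)
    fits_full = _stage("fit_psychometric")(psychometrics.curves_by_condition)(kept)
    fits_by_freq = _stage("fit_psychometric")(psychometrics.curves_by_condition)(
        kept, collapse=("amplitude_N",)
    )
    stats = _stage("stats")(experiment_stats)(fits_full, fits_by_freq, kept)
    slopes = _stage("slopes")(stats_analysis.per_subject_slopes)(
        fits_by_freq, "cv", "subject", "frequency_Hz"
    )

    bundle: dict[str, Any] = {
        "modality": modality,
        "trials": trials,
        "trials_kept": kept,
        "exclusions": exclusions,
        "fits": fits_full,
        "fits_by_frequency": fits_by_freq,
        "stats": stats,
        "cv_slopes": slopes,
    }

    if not skip_ddm:
        ddm_rows = []
        for (subj, freq), g in kept.groupby(["subject", "frequency_Hz"]):
            fit = ddm_fit.fit_ddm_condition(g, seed=seed, **config.get("ddm", {}))
            ddm_rows.append({"subject": subj, "frequency_Hz": freq, **fit.as_row()})
        ddm_fits = pd.DataFrame(ddm_rows)
        pslopes = ddm_fit.parameter_slopes(ddm_fits)
        joined = pslopes.join(slopes, how="inner")
        bundle["ddm_fits"] = ddm_fits
        bundle["parameter_slopes"] = pslopes
        bundle["slope_correlations"] = {
            p: ddm_fit.slope_behaviour_correlation(
                joined[f"slope_{p}"], joined["slope"]
            )
            for p in ("v_abs_mean", "a")
        }
        stats["slope_correlations"] = bundle["slope_correlations"]

    if outdir is not None:
        for name, df in (
            ("trials.csv", trials),
            ("exclusions.csv", exclusions),
            ("fits.csv", fits_full),
            ("fits_by_frequency.csv", fits_by_freq),
            ("cv_slopes.csv", slopes.reset_index()),
        ):
            path = outdir / name
            df.to_csv(path, index=False)
            manifest.record(path)
        if "ddm_fits" in bundle:
            path = outdir / "ddm_fits.csv"
            bundle["ddm_fits"].to_csv(path, index=False)
            manifest.record(path)
        stats_path = outdir / "stats.json"
        stats_path.write_text(json.dumps(stats, indent=2, default=float))
        manifest.record(stats_path)
        manifest.write(outdir / "manifest.json")
    bundle["manifest"] = manifest
    return bundle


#: the three qualitative signatures of the scaling study
def _signatures(target: str, cv_table: pd.DataFrame, summary: pd.DataFrame) -> dict:
    cv = cv_table.sort_values("level")["cv"].to_numpy()
    findings = {"cv_by_level": cv.tolist()}
    if target in ("v", "a", "alpha"):
        findings["cv_increases_with_level"] = bool(np.all(np.diff(cv) > 0))
    if target == "a":
        rt = summary.pivot_table(index="duration_ms", columns="level", values="rt_mean")
        findings["rt_uniformly_faster"] = bool(
            (rt.diff(axis=1).iloc[:, 1:] < 0).all().all()
        )
    return findings


def run_scaling_study(
    config: dict | None = None, outdir: str | Path | None = None
) -> dict[str, Any]:
    """Three-level scaling study for each target parameter (v, a, alpha).

    ``config`` keys: ``n_per_level`` (trials per duration per level,
    default 50,000), ``seed``, ``targets``, ``base`` (kwargs for
    :func:`~tremortime.levy_ddm.default_base_params`).  Each target's
    summary table, per-level BP/CV and the qualitative signature findings
    are returned; with ``outdir`` they are also written to CSV/JSON.
    """
    config = dict(config or {})
    n_per_level = int(config.get("n_per_level", 50_000))
    seed = int(config.get("seed", 0))
    targets = config.get("targets", ("v", "a", "alpha"))
    base = levy_ddm.default_base_params(**config.get("base", {}))

    results: dict[str, Any] = {"config": config}
    rng = np.random.default_rng(seed)
    for target in targets:
        summary = levy_ddm.scaling_study(base, target, n_per_level, rng)
        cv_table = levy_ddm.scaling_study_cv(summary)
        results[target] = {
            "summary": summary,
            "cv": cv_table,
            "findings": _signatures(target, cv_table, summary),
        }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        findings = {}
        for target in targets:
            results[target]["summary"].to_csv(
                outdir / f"scaling_{target}_summary.csv", index=False
            )
            results[target]["cv"].to_csv(outdir / f"scaling_{target}_cv.csv", index=False)
            findings[target] = results[target]["findings"]
        (outdir / "scaling_findings.json").write_text(
            json.dumps(findings, indent=2, default=float)
        )
    return results
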