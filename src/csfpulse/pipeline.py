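"""End-to-end cohort analysis driver.

``analyze_subject`` takes one subject's three waveforms through
normalization, scalar metrics, feature points, harmonic analysis,
transfer-function identification and latency estimation;
``run_cohort_study`` does this for seeded young/elderly synthetic cohorts
and adds the group-level statistics. Every stage decision is appended to a
structured log, and the whole run is reproducible from (config, seed).
"""

from __future__ import annotations

import numpy as np

from . import coupling as cp
from .io import PipelineConfig
from .spectral import calibrate_noise_threshold, dft_components
from .stats import mann_whitney, rm_anova_gg
from .synthetic import generate_cohort
from .templates import default_cohort_spec
from .waveform import (
    MissingFeatureError,
    detect_feature_points,
    normalize_amplitude,
    normalize_time,
    scalar_metrics,
)

__all__ = ["flow_from_series", "analyze_subject", "run_cohort_study"]


def flow_from_series(series, roi, reference_region=None, log: list | None = None):
    """Image-domain front end: velocity series -> flow waveform.

    Composes aliasing correction, compartment-appropriate segmentation
    (frame-by-frame Otsu for arteries, temporal-frequency segmentation for
    the spinal canal, single-frame Otsu for the aqueduct) with rim-driven
    threshold iteration, background phase correction (rectangle when
    ``reference_region`` = (r0, r1, c0, c1) is given, else the one-voxel
    contour), and flow integration.
    """
    from .image import (
        compute_flow,
        correct_background,
        iterative_segmentation,
        rim_check,
        segment_spinal_frequency,
        unwrap_velocity,
    )

    log = log if log is not None else []
    series = unwrap_velocity(series)
    comp = series.compartment
    if comp == "spinal":
        mask = segment_spinal_frequency(series, roi)
        report = rim_check(series, mask)
    else:
        mode = "per_frame" if comp == "arterial" else "single_frame"
        mask, report = iterative_segmentation(series, roi, mode=mode)
    log.append({"stage": "segment", "compartment": comp,
                "rim_passed": report.passed, "suggestion": report.suggestion})
    reference = "rectangle" if reference_region is not None else "contour"
    series = correct_background(series, mask, reference, reference_region)
    log.append({"stage": "background", "compartment": comp,
                "offset_cm_s": series.meta["background_offset_cm_s"]})
    return compute_flow(series, mask)


def analyze_subject(
    arterial,
    spinal,
    aqueduct,
    config: PipelineConfig | None = None,
    log: list | None = None,
):
    """Full single-subject analysis of the three flow waveforms.

    Scalar metrics are computed on the native cycles; amplitude
    normalization (systolic average for arterial, cycle average for CSF)
    and temporal normalization (nominal 1 s, 10 ms) precede the frequency,
    transfer-function and cross-correlation analyses.
    """
    config = config or PipelineConfig()
    log = log if log is not None else []
    waves = {"arterial": arterial, "spinal": spinal, "aqueduct": aqueduct}
    out: dict = {"metrics": {}, "features": {}, "spectra": {}, "tf": {}, "delays": {}}

    for comp, w in waves.items():
        m = scalar_metrics(w)
        out["metrics"][comp] = {
            "average_flow_ml_min": m.average_flow_ml_min,
            "net_flow_ml_min": m.net_flow_ml_min,
            "stroke_volume_ul": m.stroke_volume_ul,
        }
    aq = out["metrics"]["aqueduct"]
    aq["stroke_volume_above_threshold"] = (
        aq["stroke_volume_ul"] > config.stroke_volume_threshold_ul
    )
    aq["average_flow_above_threshold"] = (
        aq["average_flow_ml_min"] > config.average_flow_threshold_ml_min
    )

    norm = {}
    for comp, w in waves.items():
        mode = "systolic_average" if comp == "arterial" else "cc_average"
        n = normalize_time(
            normalize_amplitude(w, mode), config.nominal_cycle_ms, config.resample_dt_ms
        )
        norm[comp] = n
        log.append(
            {
                "stage": "normalize",
                "compartment": comp,
                "mode": mode,
                "native_period_ms": n.meta["native_period_ms"],
                "norm_factor_ml_s": n.meta["amplitude_norm_factor_ml_s"],
            }
        )
        try:
            feats = detect_feature_points(n, comp)
            out["features"][comp] = {
                lbl: {"time_ms": t, "amplitude": a} for lbl, (t, a) in feats.points.items()
            }
        except MissingFeatureError as err:
            out["features"][comp] = None
            log.append({"stage": "features", "compartment": comp, "missing": err.missing})
        spec = dft_components(n, config.component_counts[comp])
        out["spectra"][comp] = {
            "frequencies_hz": spec.frequencies_hz.tolist(),
            "magnitudes": spec.magnitudes.tolist(),
        }

    for comp in ("spinal", "aqueduct"):
        limit = config.noise_limit_hz[comp]
        model = cp.identify_tf(
            norm["arterial"], norm[comp], order=config.tf_order, band_limit_hz=limit
        )
        curve = cp.bode(
            model, np.arange(config.bode_df_hz, limit + 1e-9, config.bode_df_hz), limit
        )
        fco = cp.crossover_frequency(curve)
        out["tf"][comp] = {
            "b": model.b.tolist(),
            "f": model.f.tolist(),
            "stable": model.is_stable(),
            "variance_accounted_pct": model.variance_accounted_pct,
            "crossover_hz": fco,
            "gain_at_0p5_hz": float(curve.gain[np.argmin(np.abs(curve.frequencies_hz - 0.5))]),
            "gain_at_5_hz": float(curve.gain[np.argmin(np.abs(curve.frequencies_hz - 5.0))]),
        }
        log.append({"stage": "tf", "compartment": comp, "crossover_hz": fco,
                    "converged": model.converged})
        d = cp.transmission_delay(norm["arterial"], norm[comp])
        out["delays"][comp] = {
            "delay_ms": d["delay_ms"],
            "peak_to_peak_ms": d["peak_to_peak_ms"],
            "peak_correlation": d["correlation"].peak_value,
        }
    out["normalized"] = norm
    return out


def run_cohort_study(config: PipelineConfig | None = None, cohorts: dict | None = None):
    """Analyze seeded young/elderly synthetic cohorts and compare the groups.

    ``cohorts`` may map group -> list of subject dicts (as produced by
    :func:`csfpulse.synthetic.generate_cohort`); by default both packaged
    cohorts are generated with the config seed. Returns a JSON-serializable
    report with per-subject results, group summaries (delays, crossovers,
    clinical metrics) and group statistics, plus the stage log.
    """
    config = config or PipelineConfig()
    log: list = []
    if cohorts is None:
        cohorts = {}
        for i, group in enumerate(("young", "elderly")):
            spec = default_cohort_spec(group, seed=config.seed + i)
            spec.n_subjects = config.n_subjects
            cohorts[group] = generate_cohort(group, cohort=spec)
            log.append({"stage": "simulate", "group": group, "seed": spec.seed,
                        "n_subjects": spec.n_subjects})
    if not cohorts or any(len(subs) == 0 for subs in cohorts.values()):
        raise ValueError("empty input set")

    report: dict = {"groups": {}, "stats": {}, "log": log}
    summaries: dict = {}
    for group, subjects in cohorts.items():
        rows = []
        for sub in subjects:
            res = analyze_subject(
                sub["arterial"], sub["spinal"], sub["aqueduct"], config, log
            )
            res.pop("normalized")
            res["subject_id"] = sub.get("subject_id")
            res["sex"] = sub.get("sex")
            res["age_years"] = sub.get("age_years")
            res["heart_period_ms"] = sub.get("heart_period_ms")
            rows.append(res)
        noise_sds = {
            comp: [max(s[comp].meta.get("noise_sd_ml_s", 0.0), 1e-6) for s in subjects]
            for comp in ("arterial", "spinal", "aqueduct")
        }
        calib = calibrate_noise_threshold(noise_sds)
        summary = {
            "n": len(rows),
            "spinal_delay_ms": _mean_sd([r["delays"]["spinal"]["delay_ms"] for r in rows]),
            "aqueduct_delay_ms": _mean_sd([r["delays"]["aqueduct"]["delay_ms"] for r in rows]),
            "spinal_crossover_hz": _mean_sd(
                [r["tf"]["spinal"]["crossover_hz"] for r in rows]
            ),
            "aqueduct_crossover_hz": _mean_sd(
                [r["tf"]["aqueduct"]["crossover_hz"] for r in rows]
            ),
            "aqueduct_stroke_volume_ul": _mean_sd(
                [r["metrics"]["aqueduct"]["stroke_volume_ul"] for r in rows]
            ),
            "aqueduct_average_flow_ml_min": _mean_sd(
                [r["metrics"]["aqueduct"]["average_flow_ml_min"] for r in rows]
            ),
            "noise_thresholds": calib.thresholds,
        }
        report["groups"][group] = {"subjects": rows, "summary": summary}
        summaries[group] = rows

    if {"young", "elderly"} <= set(summaries):
        y, e = summaries["young"], summaries["elderly"]
        for comp in ("spinal", "aqueduct"):
            report["stats"][f"{comp}_delay_mw"] = _result_dict(
                mann_whitney(
                    [r["delays"][comp]["delay_ms"] for r in y],
                    [r["delays"][comp]["delay_ms"] for r in e],
                )
            )
            Y = np.array(
                [r["spectra"][comp]["magnitudes"] for r in y]
                + [r["spectra"][comp]["magnitudes"] for r in e]
            )
            groups = ["young"] * len(y) + ["elderly"] * len(e)
            anova = rm_anova_gg(Y, groups)
            report["stats"][f"{comp}_frequency_anova"] = {
                k: _result_dict(v) for k, v in anova.items()
            }
    return report


def _mean_sd(values):
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return {"mean": float("nan"), "sd": float("nan"), "n": 0}
    return {"mean": float(v.mean()), "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "n": int(v.size)}


def _result_dict(res):
    return {
        "statistic": res.statistic,
        "p_value": res.p_value,
        "significant": res.significant,
        **{k: v for k, v in res.extras.items()},
    }
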