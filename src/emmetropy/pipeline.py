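"""Orchestration: configuration, the simulate -> analyze -> report run, and
the run manifest.

A run config is a nested mapping (typically loaded from YAML) with a global
``seed`` plus one optional section per modality (``omr``, ``erg``, ``oct``,
``layers``, ``qpcr``).  Unknown keys anywhere are rejected before any stage
runs.  Stages execute in a fixed order, each writing tidy CSV outputs (UTF-8,
comma-separated, header row, "." decimal) into the output directory; the run
manifest -- config snapshot, package version, per-stage seeds, SHA-256 of
every output file, warnings -- is written last and suffices to reproduce the
run byte-identically.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, erg, layers, oct, omr, qpcr, synthgen, tuning
from .exceptions import EmmetropyError, InvalidInputError, InvalidSpecError

log = logging.getLogger("emmetropy")

STAGE_ORDER = ("omr", "erg", "oct", "layers", "qpcr")

_ALLOWED_KEYS = {
    "": {"seed", "log_level", *STAGE_ORDER},
    "omr": {
        "n_fish_per_group",
        "groups",
        "noise_sd_omi",
        "frequencies",
        "trials_per_condition",
        "reference_group",
        "reference_frequency",
    },
    "omr.groups[]": {"label", "amplitude", "peak_frequency", "bandwidth"},
    "erg": {"n_eyes_per_group", "groups", "noise_sd", "intensity"},
    "erg.groups[]": {
        "label",
        "a_scale",
        "a_time_to_trough",
        "b_scale",
        "b_time_to_peak",
    },
    "oct": {
        "n_eyes_per_group",
        "groups",
        "jitter_sd",
        "control_group",
        "from_bscan",
        "px_per_um",
    },
    "oct.groups[]": {
        "label",
        "cornea_pos",
        "anterior_lens_pos",
        "posterior_lens_pos",
        "rpe_pos",
    },
    "layers": {"n_images_per_group", "groups", "noise_sd", "scheme"},
    "layers.groups[]": {"label", "layer_mean_intensities", "layer_widths_px"},
    "qpcr": {
        "genes",
        "fold_changes",
        "n_samples_per_group",
        "n_replicates",
        "ct_noise_sd",
        "reference_gene",
        "calibrator_group",
    },
}


class PipelineStageError(EmmetropyError):
    """A stage failed; partial outputs of earlier stages are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def validate_config(config: dict) -> dict:
    """Reject unknown keys at every level before any stage runs."""
    if not isinstance(config, dict):
        raise InvalidSpecError("config must be a mapping")
    unknown = set(config) - _ALLOWED_KEYS[""]
    if unknown:
        raise InvalidSpecError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in config:
        raise InvalidSpecError("config needs a seed")
    for section in STAGE_ORDER:
        sub = config.get(section)
        if sub is None:
            continue
        bad = set(sub) - _ALLOWED_KEYS[section]
        if bad:
            raise InvalidSpecError(f"unknown keys in [{section}]: {sorted(bad)}")
        group_keys = _ALLOWED_KEYS.get(f"{section}.groups[]")
        if group_keys and "groups" in sub:
            for g in sub["groups"]:
                bad = set(g) - group_keys
                if bad:
                    raise InvalidSpecError(
                        f"unknown keys in [{section}] group: {sorted(bad)}"
                    )
    return config


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return validate_config(yaml.safe_load(fh))


def _stage_seeds(seed: int) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    return {stage: int(rng.integers(2**31)) for stage in STAGE_ORDER}


# ---------------------------------------------------------------------------
# Stages (each returns {filename: DataFrame} which run_pipeline writes)


def _run_omr(cfg: dict, seed: int) -> dict[str, pd.DataFrame]:
    groups = tuple(
        synthgen.GroupTuning(
            label=g["label"],
            amplitude=float(g["amplitude"]),
            peak_frequency=float(g["peak_frequency"]),
            bandwidth=float(g["bandwidth"]),
        )
        for g in cfg["groups"]
    )
    spec = synthgen.CohortSpec(
        n_fish_per_group=int(cfg["n_fish_per_group"]),
        groups=groups,
        noise_sd_omi=float(cfg.get("noise_sd_omi", 0.1)),
        seed=seed,
    )
    freqs = cfg.get("frequencies", synthgen.OMR_FREQUENCIES)
    trajectories, truth = synthgen.gen_omr_cohort(
        spec, freqs, int(cfg.get("trials_per_condition", 4))
    )
    results = [omr.compute_omi(t) for t in trajectories]
    ds = omr.build_tuning_dataset(results)
    ds = omr.normalize_omi(
        ds,
        reference_group=cfg["reference_group"],
        reference_frequency=float(cfg["reference_frequency"]),
    )
    by_group = tuning.dataset_groups(ds)
    fit_rows = []
    for label, (f, y) in by_group.items():
        fit = tuning.fit_log_gaussian(f, y)
        fit_rows.append(
            {
                "group": label,
                "amplitude": fit.amplitude,
                "peak_frequency": fit.peak_frequency,
                "bandwidth": fit.bandwidth,
                "rss": fit.rss,
                "n_points": fit.n_points,
                "r_squared": fit.r_squared,
                "flags": ";".join(fit.flags),
            }
        )
    test_rows = []
    if len(by_group) >= 2:
        comparisons = [tuning.omnibus_f_test(by_group)] + [
            tuning.nested_f_test(by_group, p) for p in tuning.PARAMETERS
        ]
        for c in comparisons:
            test_rows.append(
                {
                    "comparison": c.comparison_kind,
                    "f_statistic": c.f_statistic,
                    "df_num": c.df_num,
                    "df_den": c.df_den,
                    "p_value": c.p_value,
                    "rss_full": c.rss_full,
                    "rss_restricted": c.rss_restricted,
                }
            )
    return {
        "tuning_dataset.csv": ds[omr.DATASET_COLUMNS],
        "tuning_truth.csv": truth,
        "tuning_fits.csv": pd.DataFrame(fit_rows),
        "tuning_tests.csv": pd.DataFrame(test_rows),
    }


def _run_erg(cfg: dict, seed: int) -> dict[str, pd.DataFrame]:
    rng = np.random.default_rng(seed)
    n_eyes = int(cfg.get("n_eyes_per_group", 12))
    noise = float(cfg.get("noise_sd", 5.0))
    intensity = float(cfg.get("intensity", 1.87))
    rows = []
    avg_parts = []
    for g in cfg["groups"]:
        traces = []
        for i in range(n_eyes):
            spec = synthgen.ErgComponentSpec(
                a_scale=float(g.get("a_scale", 100.0)),
                a_time_to_trough=float(g.get("a_time_to_trough", 20.0)),
                b_scale=float(g.get("b_scale", 300.0)),
                b_time_to_peak=float(g.get("b_time_to_peak", 60.0)),
                noise_sd=noise,
                seed=int(rng.integers(2**31)),
            )
            trace, truth = synthgen.gen_erg_trace(
                spec,
                intensity=intensity,
                eye_id=f"{g['label']}_e{i:03d}",
                group=g["label"],
            )
            traces.append(trace)
            feats = erg.extract_features(trace)
            rows.append(
                {
                    "eye_id": trace.eye_id,
                    "group": g["label"],
                    "intensity": intensity,
                    "a_amplitude": feats.a_amplitude,
                    "b_amplitude": feats.b_amplitude,
                    "a_implicit_time": feats.a_implicit_time,
                    "b_implicit_time": feats.b_implicit_time,
                    "true_a_amplitude": truth["a_amplitude"],
                    "true_b_amplitude": truth["b_amplitude"],
                    "flags": ";".join(feats.flags),
                }
            )
        avg = erg.group_average(traces)
        avg.insert(0, "group", g["label"])
        avg_parts.append(avg)
    return {
        "erg_features.csv": pd.DataFrame(rows),
        "erg_group_average.csv": pd.concat(avg_parts, ignore_index=True),
    }


def _run_oct(cfg: dict, seed: int) -> dict[str, pd.DataFrame]:
    rng = np.random.default_rng(seed)
    n_eyes = int(cfg.get("n_eyes_per_group", 20))
    jitter = float(cfg.get("jitter_sd", 2.0))
    from_bscan = bool(cfg.get("from_bscan", False))
    px_per_um = float(cfg.get("px_per_um", 0.5))
    landmark_list = []
    for g in cfg["groups"]:
        for i in range(n_eyes):
            spec = synthgen.EyeGeometrySpec(
                cornea_pos=float(g.get("cornea_pos", 0.0)),
                anterior_lens_pos=float(g.get("anterior_lens_pos", 50.0)),
                posterior_lens_pos=float(g.get("posterior_lens_pos", 550.0)),
                rpe_pos=float(g.get("rpe_pos", 900.0)),
                jitter_sd=jitter,
                seed=int(rng.integers(2**31)),
            )
            eye_id = f"{g['label']}_e{i:03d}"
            if from_bscan:
                image, _ = synthgen.gen_bscan(spec, px_per_um=px_per_um)
                det = oct.detect_axis_landmarks(image, eye_id=eye_id, group=g["label"])
                lm = oct.OctLandmarks(
                    *(np.array(det.as_tuple()) / px_per_um).tolist(),
                    eye_id=eye_id,
                    group=g["label"],
                )
            else:
                lm = synthgen.gen_oct_landmarks(spec, eye_id=eye_id, group=g["label"])
            landmark_list.append(lm)
    biom = oct.biometry_table(landmark_list)
    control = cfg["control_group"]
    ctrl_ratios = biom.loc[biom["group"] == control, "rl_ratio"]
    refr_rows = []
    for label in biom["group"].unique():
        if label == control:
            continue
        summary = oct.relative_refraction(
            biom.loc[biom["group"] == label, "rl_ratio"], ctrl_ratios
        )
        refr_rows.append({"group": label, "control_group": control, **summary})
    return {
        "oct_biometry.csv": biom,
        "oct_refraction.csv": pd.DataFrame(refr_rows),
    }


def _run_layers(cfg: dict, seed: int) -> dict[str, pd.DataFrame]:
    rng = np.random.default_rng(seed)
    n_images = int(cfg.get("n_images_per_group", 12))
    noise = float(cfg.get("noise_sd", 0.05))
    scheme = cfg.get("scheme", "2-day")
    rows = []
    for g in cfg["groups"]:
        for i in range(n_images):
            spec = synthgen.LayerImageSpec(
                layer_mean_intensities=tuple(
                    g.get("layer_mean_intensities", (0.5, 1.0, 0.25))
                ),
                layer_widths_px=tuple(g.get("layer_widths_px", (90, 210, 90))),
                noise_sd=noise,
                seed=int(rng.integers(2**31)),
            )
            image, truth = synthgen.gen_layer_image(spec)
            _, sums = layers.quantify(
                image,
                scheme=scheme,
                ipl_bounds=truth["ipl_bounds"],
                eye_id=f"{g['label']}_e{i:03d}",
                group=g["label"],
            )
            rows.append(
                {
                    "eye_id": f"{g['label']}_e{i:03d}",
                    "group": g["label"],
                    "scheme": sums.window_scheme,
                    "acl_sum": sums.acl_sum,
                    "ipl_sum": sums.ipl_sum,
                    "gcl_sum": sums.gcl_sum,
                }
            )
    return {"layer_sums.csv": pd.DataFrame(rows)}


def _run_qpcr(cfg: dict, seed: int) -> dict[str, pd.DataFrame]:
    spec = synthgen.QpcrDesignSpec(
        genes=tuple(cfg["genes"]),
        fold_changes={g: dict(f) for g, f in cfg["fold_changes"].items()},
        n_samples_per_group=int(cfg.get("n_samples_per_group", 4)),
        n_replicates=int(cfg.get("n_replicates", 3)),
        ct_noise_sd=float(cfg.get("ct_noise_sd", 0.0)),
        reference_gene=cfg.get("reference_gene", "ef1a"),
        calibrator_group=cfg.get("calibrator_group"),
        seed=seed,
    )
    table, truth = synthgen.gen_ct_table(spec)
    expr = qpcr.expression_table(
        table,
        reference_gene=spec.reference_gene,
        calibrator_group=truth["calibrator_group"],
    )
    return {"qpcr_ct.csv": table, "qpcr_expression.csv": expr}


_STAGE_RUNNERS = {
    "omr": _run_omr,
    "erg": _run_erg,
    "oct": _run_oct,
    "layers": _run_layers,
    "qpcr": _run_qpcr,
}


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute configured stages in order; write tidy CSVs, report, manifest."""
    config = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(int(config["seed"]))
    written: list[Path] = []
    warnings: list[str] = []
    failed_stage = None
    try:
        for stage in STAGE_ORDER:
            if config.get(stage) is None:
                continue
            log.info("running stage %s (seed %d)", stage, seeds[stage])
            try:
                outputs = _STAGE_RUNNERS[stage](config[stage], seeds[stage])
            except Exception as exc:
                failed_stage = stage
                raise PipelineStageError(stage, exc) from exc
            for name, frame in outputs.items():
                path = out / name
                frame.to_csv(path, index=False)
                written.append(path)
        report = make_report(out)
        report_path = out / "report.txt"
        report_path.write_text(report, encoding="utf-8")
        written.append(report_path)
    finally:
        manifest = {
            "config": config,
            "version": __version__,
            "stage_seeds": seeds,
            "outputs": {
                p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in written
            },
            "warnings": warnings,
            "status": "failed at stage " + failed_stage if failed_stage else "ok",
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
        )
    return manifest


# ---------------------------------------------------------------------------
# Report


def _mean_sem(series) -> str:
    vals = np.asarray(series, dtype=float)
    m = vals.mean()
    if vals.size > 1:
        sem = vals.std(ddof=1) / np.sqrt(vals.size)
        return f"{m:.4g} +/- {sem:.2g} (n={vals.size})"
    return f"{m:.4g} (n=1)"


def make_report(out_dir) -> str:
    """Human-readable summary recomputed from the tidy stage outputs."""
    out = Path(out_dir)
    sections = []

    path = out / "tuning_fits.csv"
    if path.exists():
        fits = pd.read_csv(path)
        lines = ["== Spatial-frequency tuning =="]
        for _, r in fits.iterrows():
            lines.append(
                f"  {r['group']}: amplitude={r['amplitude']:.4g}, "
                f"peak={r['peak_frequency']:.4g} c/deg, "
                f"bandwidth={r['bandwidth']:.4g} log10-units, r2={r['r_squared']:.3f}"
            )
        if len(fits) >= 2:
            amax = fits.loc[fits["amplitude"].idxmax(), "group"]
            amin = fits.loc[fits["amplitude"].idxmin(), "group"]
            if fits["amplitude"].max() > fits["amplitude"].min():
                lines.append(
                    f"  lower tuning amplitude in group '{amin}' than '{amax}'"
                )
        tests_path = out / "tuning_tests.csv"
        if tests_path.exists():
            tests = pd.read_csv(tests_path)
            for _, r in tests.iterrows():
                lines.append(
                    f"  {r['comparison']}: F({r['df_num']}, {r['df_den']}) = "
                    f"{r['f_statistic']:.4g}, p = {r['p_value']:.4g}"
                )
        sections.append("\n".join(lines))

    path = out / "erg_features.csv"
    if path.exists():
        feats = pd.read_csv(path)
        lines = ["== ERG features =="]
        for label, g in feats.groupby("group"):
            lines.append(
                f"  {label}: a-wave {_mean_sem(g['a_amplitude'])} uV, "
                f"b-wave {_mean_sem(g['b_amplitude'])} uV, "
                f"a-time {_mean_sem(g['a_implicit_time'])} ms, "
                f"b-time {_mean_sem(g['b_implicit_time'])} ms"
            )
        sections.append("\n".join(lines))

    path = out / "oct_biometry.csv"
    if path.exists():
        biom = pd.read_csv(path)
        lines = ["== OCT biometry =="]
        for label, g in biom.groupby("group"):
            lines.append(
                f"  {label}: axial {_mean_sem(g['axial_length_um'])} um, "
                f"R/L ratio {_mean_sem(g['rl_ratio'])}"
            )
        refr_path = out / "oct_refraction.csv"
        if refr_path.exists():
            refr = pd.read_csv(refr_path)
            for _, r in refr.iterrows():
                lines.append(
                    f"  {r['group']} vs {r['control_group']}: "
                    f"R/L shift {r['mean_shift']:+.4g} -> {r['label']}"
                )
        sections.append("\n".join(lines))

    path = out / "layer_sums.csv"
    if path.exists():
        sums = pd.read_csv(path)
        lines = ["== Inner-retinal layer sums =="]
        for label, g in sums.groupby("group"):
            lines.append(
                f"  {label}: ACL {_mean_sem(g['acl_sum'])}, "
                f"IPL {_mean_sem(g['ipl_sum'])}, GCL {_mean_sem(g['gcl_sum'])}"
            )
        sections.append("\n".join(lines))

    path = out / "qpcr_expression.csv"
    if path.exists():
        expr = pd.read_csv(path)
        lines = ["== Relative expression (2^-ddCt) =="]
        for (gene, label), g in expr.groupby(["gene", "group"]):
            lines.append(f"  {gene} in {label}: fold {_mean_sem(g['fold_change'])}")
        sections.append("\n".join(lines))

    if not sections:
        raise InvalidInputError(f"no stage outputs found in {out}")
    return "\n\n".join(sections) + "\n"


# ---------------------------------------------------------------------------
# Demo configuration


def demo_config(seed: int = 0) -> dict:
    """Two-group study: mutant with a 30% tuning-amplitude deficit and an
    elevated R/L ratio, against an otherwise identical control."""
    return {
        "seed": seed,
        "omr": {
            "n_fish_per_group": 14,
            "noise_sd_omi": 0.1,
            "reference_group": "control",
            "reference_frequency": 0.0155,
            "groups": [
                {
                    "label": "control",
                    "amplitude": 1.0,
                    "peak_frequency": 0.062,
                    "bandwidth": 0.3,
                },
                {
                    "label": "mutant",
                    "amplitude": 0.7,
                    "peak_frequency": 0.062,
                    "bandwidth": 0.3,
                },
            ],
        },
        "erg": {
            "n_eyes_per_group": 12,
            "noise_sd": 5.0,
            "groups": [
                {"label": "control", "a_scale": 100.0, "b_scale": 300.0},
                {"label": "mutant", "a_scale": 70.0, "b_scale": 250.0},
            ],
        },
        "oct": {
            "n_eyes_per_group": 20,
            "jitter_sd": 2.0,
            "control_group": "control",
            "groups": [
                {"label": "control", "rpe_pos": 900.0},
                # lens radius 250 um; retinal radius 675 um -> R/L 2.7 (+0.1)
                {"label": "mutant", "rpe_pos": 925.0},
            ],
        },
        "layers": {
            "n_images_per_group": 12,
            "noise_sd": 0.05,
            "scheme": "2-day",
            "groups": [
                {"label": "control", "layer_mean_intensities": [0.5, 1.0, 0.25]},
                {"label": "mutant", "layer_mean_intensities": [0.35, 1.0, 0.25]},
            ],
        },
        "qpcr": {
            "genes": ["ef1a", "efemp1", "egr1"],
            "reference_gene": "ef1a",
            "calibrator_group": "control",
            "ct_noise_sd": 0.1,
            "fold_changes": {
                "control": {"efemp1": 1.0, "egr1": 1.0},
                "mutant": {"efemp1": 0.5, "egr1": 2.0},
            },
        },
    }
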