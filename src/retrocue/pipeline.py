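"""End-to-end orchestration: simulate -> preprocess -> analyze -> report.

A run is configured by one :class:`RunConfig`, executed by
:func:`run_pipeline`, and lands in a run directory containing every stage's
artifacts (EpochSet containers, CSV/JSON summaries), a frozen copy of the
resolved configuration, a SHA-256 manifest of all artifacts, a plain-text
log, and a markdown report whose numbers are read back from the artifact
files (the report layer recomputes nothing).

Group-level statistics treat independent generator seeds as "subjects":
``n_virtual_subjects`` datasets are generated from per-subject seeds and
the scalar measures and decoding curves are compared across them exactly as
across participants in a real study.

Seed derivation: every source of randomness is a child of the global seed.
Stage s for subject i uses ``SeedSequence((global_seed, STAGE_IDS[s], i))``;
the first 31-bit word of its state is the stage seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from retrocue import behavior as beh
from retrocue import decoding as dec
from retrocue import evoked as evk
from retrocue import preprocess as pre
from retrocue import spectral as spc
from retrocue import stats as st
from retrocue.containers import (
    EpochSet,
    HEOG_NAME,
    PARIETO_OCCIPITAL,
    load_epochs,
    save_epochs,
)
from retrocue.synth import SynthConfig, attach_behavior, generate_behavior, generate_epochs

STAGE_IDS = {
    "simulate": 1,
    "preprocess": 2,
    "behavior": 3,
    "decoding": 4,
    "tgm": 5,
    "evoked": 6,
    "spectral": 7,
    "stats": 8,
}

DEFAULT_STAGES = {name: True for name in STAGE_IDS} | {"tgm": False}


def stage_seed(global_seed: int, stage: str, subject: int = 0) -> int:
    """Deterministic 31-bit child seed for a stage x subject."""
    ss = np.random.SeedSequence((global_seed, STAGE_IDS[stage], subject))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Declarative configuration of one end-to-end run."""

    seed: int = 0
    out_dir: str = "runs/retrocue"
    n_virtual_subjects: int = 1
    synth: SynthConfig = field(default_factory=SynthConfig)
    stages: dict = field(default_factory=lambda: dict(DEFAULT_STAGES))

    # preprocessing
    band: tuple[float, float] = (0.1, 40.0)
    baseline: tuple[float, float] = (-200.0, 0.0)
    amp_thresh_uv: float = 80.0
    heog_thresh_uv: float = 50.0

    # decoding
    decode_features: tuple[str, ...] = ("target_orientation",)
    decode_conditions: tuple[str, ...] = ("valid", "neutral")
    n_bins: int = 3
    n_folds: int = 3
    n_iterations: int = 10
    downsample_to: float = 50.0
    tgm_features: tuple[str, ...] = ("target_space", "target_color")

    # evoked / spectral windows
    n2_window: tuple[float, float] = (320.0, 360.0)
    n600_window: tuple[float, float] = (600.0, 1300.0)
    alpha_band: tuple[float, float] = (8.0, 12.0)
    alpha_window: tuple[float, float] = (300.0, 600.0)
    itpc_band: tuple[float, float] = (3.0, 7.0)
    itpc_window: tuple[float, float] = (100.0, 700.0)
    pac_window: tuple[float, float] = (0.0, 1500.0)
    pac_n_bins: int = 18

    # behavior
    mixture_min_trials: int = 50

    # statistics
    n_perm: int = 10_000
    alpha: float = 0.05

    def validate(self) -> None:
        """Check windows and electrode references before any stage runs."""
        lo, hi = self.synth.epoch_window
        for name, win in (
            ("baseline", self.baseline),
            ("N2", self.n2_window),
            ("N600", self.n600_window),
            ("alpha ERD", self.alpha_window),
            ("ITPC", self.itpc_window),
            ("PAC", self.pac_window),
        ):
            if win[0] < lo or win[1] > hi:
                raise ValueError(
                    f"{name} window {win} outside the epoch span {lo:g}..{hi:g} ms"
                )
        for feat in (*self.decode_features, *self.tgm_features):
            if feat not in dec.FEATURES:
                raise ValueError(f"unknown decoding feature {feat!r}")
        if not 0 < self.band[0] < self.band[1] < self.synth.srate / 2:
            raise ValueError(f"infeasible filter band {self.band}")


def io_roundtrip(e: EpochSet, directory: str | Path) -> EpochSet:
    """Write an EpochSet and read it back (equality is tested, not assumed)."""
    save_epochs(e, directory)
    return load_epochs(directory)


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    return obj


class _Run:
    """Mutable state of one pipeline execution."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.root = Path(cfg.out_dir)
        self.log_lines: list[str] = []
        self.summary: dict = {}

    def log(self, msg: str) -> None:
        self.log_lines.append(msg)

    def subject_dir(self, i: int) -> Path:
        d = self.root / f"subject_{i:02d}"
        d.mkdir(parents=True, exist_ok=True)
        return d


def _stage_simulate(run: _Run, subject: int) -> EpochSet:
    cfg = run.cfg
    scfg = replace(cfg.synth, rng_seed=stage_seed(cfg.seed, "simulate", subject))
    epochs, truth = generate_epochs(scfg)
    behavior = generate_behavior(scfg, truth)
    epochs = attach_behavior(epochs, behavior)
    save_epochs(epochs, run.subject_dir(subject) / "epochs_raw")
    run.log(
        f"subject {subject}: simulated {epochs.n_trials} trials x "
        f"{epochs.n_channels} channels x {epochs.n_times} samples"
    )
    return epochs


def _stage_preprocess(run: _Run, subject: int, epochs: EpochSet) -> EpochSet:
    cfg = run.cfg
    e = pre.bandpass(epochs, *cfg.band)
    e = pre.baseline_correct(e, cfg.baseline)
    e = pre.reject_artifacts(e, cfg.amp_thresh_uv, cfg.heog_thresh_uv)
    screen = pre.screen_participant(e)
    save_epochs(e, run.subject_dir(subject) / "epochs_clean")
    counts = (
        e.kept_trials().trial_table.groupby("condition").size().to_dict()
        if "condition" in e.trial_table.columns
        else {}
    )
    run.log(
        f"subject {subject}: kept trials per condition {counts}; "
        f"reject fraction {screen.reject_fraction:.3f}; "
        f"mean HEOG {screen.mean_heog_uv:+.2f} uV; keep={screen.keep}"
    )
    run.summary.setdefault("screen", {})[str(subject)] = {
        "keep": screen.keep,
        "reject_fraction": screen.reject_fraction,
        "mean_heog_uv": screen.mean_heog_uv,
    }
    return e


def _stage_behavior(run: _Run, subject: int, epochs: EpochSet) -> pd.DataFrame:
    table = epochs.kept_trials().trial_table
    summary = beh.summarize_behavior(
        table,
        fit_seed=stage_seed(run.cfg.seed, "behavior", subject),
        min_trials=run.cfg.mixture_min_trials,
    )
    summary.insert(0, "subject", subject)
    summary.to_csv(run.subject_dir(subject) / "behavior_fit.csv", index=False)
    run.log(
        f"subject {subject}: behavior fits "
        + "; ".join(
            f"{r.condition}: pT={r.p_target:.3f} pNT={r.p_nontarget:.3f} "
            f"pU={r.p_uniform:.3f} SD={r.sd_deg:.1f}"
            for r in summary.itertuples()
        )
    )
    return summary


def _stage_decoding(run: _Run, subject: int, epochs: EpochSet) -> dict:
    cfg = run.cfg
    out = {}
    down = dec.downsample_epochs(epochs.kept_trials(), cfg.downsample_to)
    for feature in cfg.decode_features:
        for condition in cfg.decode_conditions:
            spec = dec.DecodingSpec(
                feature=feature,
                n_bins=cfg.n_bins,
                n_folds=cfg.n_folds,
                n_iterations=cfg.n_iterations,
                downsample_to=cfg.downsample_to,
                rng_seed=stage_seed(cfg.seed, "decoding", subject),
            )
            curve = dec.decode_timecourse(down, spec, condition=condition)
            df = pd.DataFrame(
                {"time_ms": curve.times, "accuracy": curve.accuracy}
            )
            df.to_csv(
                run.subject_dir(subject) / f"decoding_{feature}_{condition}.csv",
                index=False,
            )
            out[(feature, condition)] = curve
            run.log(
                f"subject {subject}: {feature}/{condition} peak accuracy "
                f"{curve.accuracy.max():.3f} (chance {curve.chance:.3f})"
            )
    return out


def _stage_tgm(run: _Run, subject: int, epochs: EpochSet) -> dict:
    cfg = run.cfg
    out = {}
    down = dec.downsample_epochs(epochs.kept_trials(), cfg.downsample_to)
    for feature in cfg.tgm_features:
        spec = dec.DecodingSpec(
            feature=feature,
            n_bins=cfg.n_bins,
            n_folds=cfg.n_folds,
            n_iterations=cfg.n_iterations,
            downsample_to=cfg.downsample_to,
            rng_seed=stage_seed(cfg.seed, "tgm", subject),
        )
        gmap = dec.decode_generalization(down, spec, condition="valid")
        profile = dec.spread_time(gmap)
        np.savetxt(
            run.subject_dir(subject) / f"tgm_{feature}_valid.csv",
            gmap.acc,
            delimiter=",",
        )
        pd.DataFrame(
            {"time_ms": profile.times, "spread_time": profile.spread_time}
        ).to_csv(
            run.subject_dir(subject) / f"spreadtime_{feature}_valid.csv", index=False
        )
        out[feature] = profile
        run.log(
            f"subject {subject}: {feature} valid-condition mean spread time "
            f"{profile.spread_time.mean():.1f} of {profile.times.size} test points"
        )
    return out


def _stage_evoked(run: _Run, subject: int, epochs: EpochSet) -> dict:
    cfg = run.cfg
    n2 = evk.ErpComponent("N2", cfg.n2_window)
    n600 = evk.ErpComponent("N600", cfg.n600_window)
    out = {}
    for condition in ("valid", "neutral"):
        erp = evk.average_erp(epochs, condition=condition, baseline=cfg.baseline)
        out[condition] = {
            "N2": evk.component_amplitude(erp, n2),
            "N600": evk.component_amplitude(erp, n600),
            "n_trials": erp.n_trials,
        }
    rt_bins = evk.rt_bin_erp(epochs, component=n2, baseline=cfg.baseline)
    rt_bins.to_csv(run.subject_dir(subject) / "erp_rt_bins.csv", index=False)
    pd.DataFrame(out).to_json(run.subject_dir(subject) / "erp_components.json")
    run.log(
        f"subject {subject}: N2 valid {out['valid']['N2']:+.2f} uV, "
        f"neutral {out['neutral']['N2']:+.2f} uV; N600 valid "
        f"{out['valid']['N600']:+.2f} uV, neutral {out['neutral']['N600']:+.2f} uV"
    )
    return out


def _stage_spectral(run: _Run, subject: int, epochs: EpochSet) -> dict:
    cfg = run.cfg
    kept = epochs.kept_trials()
    residual = spc.remove_phase_locked(kept)
    out = {}
    for condition in ("valid", "neutral"):
        mask = kept.trial_table["condition"].to_numpy() == condition
        cond_res = residual.select_trials(mask)
        cond_raw = kept.select_trials(mask)
        # non-phase-locked parieto-occipital power -> alpha ERD
        tfr = spc.erd(spc.stft_tfr(cond_res, channels=list(PARIETO_OCCIPITAL)))
        alpha_erd = tfr.band_window_mean(
            PARIETO_OCCIPITAL, cfg.alpha_band, cfg.alpha_window
        )
        # phase-locked frontal theta coherence (computed on raw epochs)
        tfr_fz = spc.stft_tfr(cond_raw, channels=["Fz"], keep_complex=True)
        theta_itpc = spc.itpc(tfr_fz).average(
            "Fz", cfg.itpc_band, cfg.itpc_window
        )
        pac = spc.pac_mi(
            kept,
            window=cfg.pac_window,
            n_bins=cfg.pac_n_bins,
            condition=condition,
        )
        out[condition] = {
            "alpha_erd_log10": alpha_erd,
            "theta_itpc": theta_itpc,
            "pac_mi": pac.mi_mean,
        }
        run.log(
            f"subject {subject}: {condition} alpha ERD {alpha_erd:+.3f} log10, "
            f"theta ITPC {theta_itpc:.3f}, PAC MI {pac.mi_mean:.4f}"
        )
    (run.subject_dir(subject) / "spectral.json").write_text(
        json.dumps(_to_jsonable(out), indent=1)
    )
    return out


def _stage_stats(run: _Run, per_subject: dict) -> dict:
    """Group statistics across virtual subjects."""
    cfg = run.cfg
    results: dict = {"scalar_tests": {}, "cluster_tests": {}}
    n_subj = cfg.n_virtual_subjects
    seed = stage_seed(cfg.seed, "stats", 0)

    def paired(name, valid_vals, neutral_vals):
        try:
            res = st.ttest(np.asarray(valid_vals), np.asarray(neutral_vals), paired=True)
        except ValueError as err:
            results["scalar_tests"][name] = {"error": str(err)}
            return
        results["scalar_tests"][name] = {
            "t": res.t,
            "df": res.df,
            "p": res.p,
            "cohens_d": res.cohens_d,
            "mean_valid": float(np.mean(valid_vals)),
            "mean_neutral": float(np.mean(neutral_vals)),
        }

    if per_subject.get("behavior"):
        b = pd.concat(per_subject["behavior"], ignore_index=True)
        for col in ("p_target", "p_uniform", "sd_deg", "mean_abs_error_deg", "mean_rt_ms"):
            pivot = b.pivot(index="subject", columns="condition", values=col)
            if {"valid", "neutral"} <= set(pivot.columns) and len(pivot) >= 3:
                paired(f"behavior/{col}", pivot["valid"], pivot["neutral"])

    for key in ("evoked", "spectral"):
        if per_subject.get(key):
            first = per_subject[key][0]
            for measure in first["valid"]:
                if measure == "n_trials":
                    continue
                v = [s["valid"][measure] for s in per_subject[key]]
                n = [s["neutral"][measure] for s in per_subject[key]]
                if len(v) >= 3:
                    paired(f"{key}/{measure}", v, n)

    if per_subject.get("decoding") and n_subj >= 5:
        by_key: dict = {}
        for curves in per_subject["decoding"]:
            for key, curve in curves.items():
                by_key.setdefault(key, []).append(curve)
        for (feature, condition), curves in by_key.items():
            stack = np.stack([c.accuracy for c in curves])
            res = st.cluster_permutation_vs_chance(
                stack,
                chance=curves[0].chance,
                n_perm=cfg.n_perm,
                seed=seed,
                alpha=cfg.alpha,
                times=curves[0].times,
            )
            results["cluster_tests"][f"{feature}/{condition}"] = {
                "clusters_ms": [
                    [float(curves[0].times[a]), float(curves[0].times[b - 1])]
                    for a, b in res.clusters
                ],
                "p_values": res.p_values.tolist(),
                "significant": [
                    [float(curves[0].times[a]), float(curves[0].times[b - 1])]
                    for a, b in res.significant()
                ],
            }

    if per_subject.get("tgm") and n_subj >= 5 and len(cfg.tgm_features) == 2:
        f1, f2 = cfg.tgm_features
        a = np.stack([s[f1].spread_time for s in per_subject["tgm"]]).astype(float)
        b = np.stack([s[f2].spread_time for s in per_subject["tgm"]]).astype(float)
        res = st.cluster_permutation_paired(
            a, b, n_perm=cfg.n_perm, seed=seed, alpha=cfg.alpha
        )
        results["cluster_tests"][f"spreadtime/{f1}_vs_{f2}"] = {
            "clusters": [list(c) for c in res.clusters],
            "p_values": res.p_values.tolist(),
            "n_significant": len(res.significant()),
        }

    # FDR across the scalar battery: the significance column of the report
    names = [n for n, r in results["scalar_tests"].items() if "p" in r]
    if names:
        reject, p_adj = st.fdr_correct(
            [results["scalar_tests"][n]["p"] for n in names], q=cfg.alpha
        )
        for n, rej, pa in zip(names, reject, p_adj):
            results["scalar_tests"][n]["p_fdr"] = float(pa)
            results["scalar_tests"][n]["significant"] = bool(rej)
    return results


def _render_report(summary: dict, path: Path) -> None:
    """Markdown report rendered purely from the summary artifact."""
    lines = ["# Retro-cue analysis report", ""]
    if "behavior" in summary:
        lines += ["## Behavior (mixture model per condition)", ""]
        lines.append("| subject | condition | pT | pNT | pU | SD (deg) | mean RT (ms) |")
        lines.append("|--:|--|--:|--:|--:|--:|--:|")
        for row in summary["behavior"]:
            lines.append(
                f"| {row['subject']} | {row['condition']} | {row['p_target']:.3f} "
                f"| {row['p_nontarget']:.3f} | {row['p_uniform']:.3f} "
                f"| {row['sd_deg']:.1f} | {row['mean_rt_ms']:.0f} |"
            )
        lines.append("")
    if "evoked" in summary:
        lines += ["## ERP components (uV)", ""]
        lines.append("| subject | condition | N2 | N600 |")
        lines.append("|--:|--|--:|--:|")
        for i, subj in enumerate(summary["evoked"]):
            for cond in ("valid", "neutral"):
                lines.append(
                    f"| {i} | {cond} | {subj[cond]['N2']:+.2f} | {subj[cond]['N600']:+.2f} |"
                )
        lines.append("")
    if "spectral" in summary:
        lines += ["## Oscillatory measures", ""]
        lines.append("| subject | condition | alpha ERD (log10) | theta ITPC | PAC MI |")
        lines.append("|--:|--|--:|--:|--:|")
        for i, subj in enumerate(summary["spectral"]):
            for cond in ("valid", "neutral"):
                m = subj[cond]
                lines.append(
                    f"| {i} | {cond} | {m['alpha_erd_log10']:+.3f} "
                    f"| {m['theta_itpc']:.3f} | {m['pac_mi']:.4f} |"
                )
        lines.append("")
    stats_block = summary.get("stats", {})
    if stats_block.get("scalar_tests"):
        lines += ["## Group comparisons (valid vs neutral, paired t)", ""]
        lines.append("| measure | t | df | p | d | significant (FDR) |")
        lines.append("|--|--:|--:|--:|--:|--|")
        for name, r in stats_block["scalar_tests"].items():
            if "error" in r:
                lines.append(f"| {name} | - | - | - | - | - |")
            else:
                sig = "yes" if r.get("significant") else "no"
                lines.append(
                    f"| {name} | {r['t']:.3f} | {r['df']} | {r['p']:.4f} "
                    f"| {r['cohens_d']:.3f} | {sig} |"
                )
        lines.append("")
    if stats_block.get("cluster_tests"):
        lines += ["## Cluster permutation tests", ""]
        for name, r in stats_block["cluster_tests"].items():
            sig = r.get("significant", r.get("n_significant"))
            lines.append(f"- **{name}**: p-values {r['p_values']}; significant: {sig}")
        lines.append("")
    path.write_text("\n".join(lines))


def _write_manifest(root: Path) -> None:
    manifest = {}
    for f in sorted(root.rglob("*")):
        if f.is_file() and f.name not in ("manifest.json", "log.txt"):
            manifest[str(f.relative_to(root))] = hashlib.sha256(
                f.read_bytes()
            ).hexdigest()
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured stages and return the run directory.

    Deterministic: identical config + seed reproduce byte-identical
    artifacts (checksummed in ``manifest.json``). Any stage failure aborts
    with the stage name.
    """
    cfg.validate()
    run = _Run(cfg)
    run.root.mkdir(parents=True, exist_ok=True)
    frozen = _to_jsonable(asdict(cfg))
    (run.root / "config.json").write_text(json.dumps(frozen, indent=1, sort_keys=True))

    stages = {**DEFAULT_STAGES, **cfg.stages}
    per_subject: dict = {k: [] for k in ("behavior", "decoding", "tgm", "evoked", "spectral")}

    for subject in range(cfg.n_virtual_subjects):
        epochs = None
        for name, fn in (
            ("simulate", _stage_simulate),
            ("preprocess", _stage_preprocess),
        ):
            if not stages.get(name, False):
                continue
            try:
                epochs = fn(run, subject) if name == "simulate" else fn(run, subject, epochs)
            except Exception as err:
                raise RuntimeError(f"stage {name!r} failed for subject {subject}: {err}") from err
        if epochs is None:
            raise RuntimeError("stage 'simulate' is required (imported data: load and pass stages manually)")
        for name, fn, store in (
            ("behavior", _stage_behavior, "behavior"),
            ("decoding", _stage_decoding, "decoding"),
            ("tgm", _stage_tgm, "tgm"),
            ("evoked", _stage_evoked, "evoked"),
            ("spectral", _stage_spectral, "spectral"),
        ):
            if not stages.get(name, False):
                continue
            try:
                per_subject[store].append(fn(run, subject, epochs))
            except Exception as err:
                raise RuntimeError(f"stage {name!r} failed for subject {subject}: {err}") from err

    if per_subject["behavior"]:
        run.summary["behavior"] = pd.concat(
            per_subject["behavior"], ignore_index=True
        ).to_dict("records")
    if per_subject["evoked"]:
        run.summary["evoked"] = per_subject["evoked"]
    if per_subject["spectral"]:
        run.summary["spectral"] = per_subject["spectral"]

    if stages.get("stats", False):
        try:
            run.summary["stats"] = _stage_stats(run, per_subject)
        except Exception as err:
            raise RuntimeError(f"stage 'stats' failed: {err}") from err

    (run.root / "summary.json").write_text(
        json.dumps(_to_jsonable(run.summary), indent=1, sort_keys=True)
    )
    _render_report(
        json.loads((run.root / "summary.json").read_text()), run.root / "report.md"
    )
    (run.root / "log.txt").write_text("\n".join(run.log_lines) + "\n")
    _write_manifest(run.root)
    return run.root
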