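"""End-to-end analysis: simulate -> preprocess -> TFR -> ERSP / PSD -> stats.

Reproduces, at desk scale, the full oscillatory-marker analysis of a
sequential conditioned pain modulation experiment: grand-average window
detection, per-participant magnitude and duration statistics, baseline
spectra, rank-based ANOVA-type tests with post hoc contrasts,
cluster-based permutation contrasts of time-frequency maps, spatial
permutation t-maps, and the behavioral-neural correlation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .ats import LongitudinalData, ats_f1_ld_f1
from .containers import Dataset, EpochedRecording
from .ersp import (
    ALPHA,
    BETA,
    Band,
    ErspWindow,
    detect_windows,
    ersp_duration,
    ersp_location_map,
    ersp_magnitude,
    pick_window,
)
from .preprocess import preprocess_recording
from .simulate import GroundTruth, SimulationConfig, generate_dataset
from .spectral import baseline_psd, compare_baselines
from .stats import (
    cluster_permutation_tfr,
    permutation_ttest_maps,
    posthoc_paired,
    spearman,
)
from .tfr import WaveletSpec, ZSpectrogram, grand_average, morlet_tfr, zscore_baseline

logger = logging.getLogger("cpmosc")

__all__ = ["RatingSpec", "AnalysisConfig", "RunReport", "run_full", "simulate_ratings"]


@dataclass
class RatingSpec:
    """Generator of 0-10 pain ratings coupled (optionally) to the
    injected beta-ERS modulation, so the neural-behavioral correlation
    analysis is exercisable under both null and non-null coupling."""

    condition_means: dict[str, float] = field(
        default_factory=lambda: {"before": 3.8, "during": 3.45, "after": 3.3}
    )
    subject_sd: float = 1.2
    noise_sd: float = 0.5
    coupling: float = 0.0  # rating points per sd of realized ERS gain


@dataclass
class AnalysisConfig:
    """All analysis constants, each overridable; numeric defaults equal
    the values of the study protocol this pipeline emulates."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    sensor_roi: list[str] | None = None  # default: simulator response channels
    brain_roi: list[str] | None = None
    alpha_band: Band = ALPHA
    beta_band: Band = BETA
    window_threshold: float = 0.5  # z, grand-average window detection
    duration_threshold: float = 2.0  # z, per-participant duration
    smooth_window: float = 0.5  # s, duration moving average
    zscore_baseline: tuple[float, float] = (-1.5, -0.5)
    psd_baseline: tuple[float, float] = (-2.0, 0.0)
    tfr_freqs: np.ndarray | None = None  # default 1..60 Hz
    tfr_decim: int = 4
    wavelet: WaveletSpec = field(default_factory=WaveletSpec)
    z_order: str = "per-trial"  # or "average-first"
    n_perm: int = 1000
    alpha: float = 0.05
    cluster_alpha: float = 0.05
    posthoc_method: str = "holm"
    preprocess: bool = True
    compute_location_maps: bool = True
    compute_psd: bool = True
    compute_clusters: bool = True
    ratings: RatingSpec = field(default_factory=RatingSpec)
    seed: int = 0

    def resolved_rois(self) -> tuple[list[str], list[str]]:
        resp = self.simulation.response_channels
        return (self.sensor_roi or resp, self.brain_roi or resp)


# The three canonical stimulus-locked perturbations: measurement ROI,
# band, sign, and a latency hint used to pick among detected windows
# (desynchronizations are early, the beta rebound late).
ERSP_DEFS = (
    ("alpha_erd", "sensor", "alpha", -1, 0.5),
    ("beta_erd", "brain", "beta", -1, 0.35),
    ("beta_ers", "brain", "beta", +1, 2.0),
)


@dataclass
class RunReport:
    windows: dict[str, dict]
    measures: pd.DataFrame
    ratings: pd.DataFrame
    summary: pd.DataFrame
    ats: dict[str, dict]
    posthoc: dict[str, dict]
    clusters: dict[str, dict]
    psd: dict[str, dict]
    correlation: dict[str, float]
    location: dict[str, dict]
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "windows": self.windows,
            "ats": self.ats,
            "posthoc": self.posthoc,
            "clusters": self.clusters,
            "psd": self.psd,
            "correlation": self.correlation,
            "location": self.location,
            "summary": self.summary.to_dict(orient="records"),
            "provenance": self.provenance,
        }

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(self.to_dict(), indent=2, default=_js))
        self.measures.to_csv(out / "ersp_measures.csv", index=False)
        self.ratings.to_csv(out / "ratings.csv", index=False)
        self.summary.to_csv(out / "summary.csv", index=False)


def _js(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _config_hash(config: AnalysisConfig) -> str:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        return obj

    blob = json.dumps(enc(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def simulate_ratings(
    spec: RatingSpec, truth: GroundTruth, seed: int
) -> pd.DataFrame:
    """Per-participant x condition subjective pain ratings in [0, 10].

    Ratings are a condition-level mean plus a subject offset plus noise;
    with nonzero ``coupling`` the rating tracks the standardized
    realized beta-ERS gain, so rating change and ERS change correlate.
    """
    rng = np.random.default_rng(seed)
    gt = truth.to_frame()
    gains = gt["beta_ers_gain"].to_numpy()
    g_sd = gains.std() or 1.0
    g_mu = gains.mean()
    rows = []
    offsets = {pid: rng.normal(0.0, spec.subject_sd) for pid in gt["participant_id"].unique()}
    for _, r in gt.iterrows():
        base = spec.condition_means[r["condition"]]
        val = (
            base
            + offsets[r["participant_id"]]
            + spec.coupling * (r["beta_ers_gain"] - g_mu) / g_sd
            + rng.normal(0.0, spec.noise_sd)
        )
        rows.append(
            {
                "participant_id": r["participant_id"],
                "group": r["group"],
                "condition": r["condition"],
                "rating": float(np.clip(val, 0.0, 10.0)),
            }
        )
    return pd.DataFrame(rows)


def _roi_zmap(rec: EpochedRecording, channels: list[str], config: AnalysisConfig):
    """Trial-averaged z-map over the given channels.

    Returns a ZSpectrogram with dims ("channel",).  In the primary
    "per-trial" order each trial's magnitude map is z-scored against its
    own baseline before averaging; "average-first" z-scores the
    trial-averaged magnitude map instead.
    """
    present = [c for c in channels if c in rec.channel_names]
    if not present:
        raise ValueError(f"none of the ROI channels {channels} present")
    spect = morlet_tfr(
        rec,
        freqs=config.tfr_freqs,
        spec=config.wavelet,
        decim=config.tfr_decim,
        channels=present,
    )
    if config.z_order == "per-trial":
        z = zscore_baseline(spect, config.zscore_baseline)
        return z.mean_over("trial")
    if config.z_order == "average-first":
        return zscore_baseline(spect.mean_over("trial"), config.zscore_baseline)
    raise ValueError(f"unknown z_order {config.z_order!r}")


def _ats_summary(measure_df: pd.DataFrame, value: str, conditions) -> dict:
    data = LongitudinalData.from_frame(
        measure_df,
        y=value,
        subject="participant_id",
        group="group",
        condition="condition",
        condition_order=list(conditions),
    )
    res = ats_f1_ld_f1(data)
    out = {}
    for name, e in res.effects().items():
        out[name] = {"statistic": e.statistic, "df": e.df_num, "p": e.p}
        if e.p_box is not None:
            out[name]["p_box"] = e.p_box
            out[name]["df_den_box"] = e.df_den_box
    out["relative_effects"] = res.relative_effects.to_dict()
    out["degenerate"] = res.degenerate
    return out


def _paired_values(df: pd.DataFrame, value: str, conditions) -> dict[str, np.ndarray]:
    wide = df.pivot_table(
        index="participant_id", columns="condition", values=value, sort=False
    )
    return {c: wide[c].to_numpy() for c in conditions}


def run_full(config: AnalysisConfig, dataset: Dataset | None = None) -> RunReport:
    """Execute the complete analysis and return the run report.

    When ``dataset`` is None, a synthetic experiment is generated from
    ``config.simulation`` (with ``config.seed``).  Every stage is a pure
    function of (inputs, config, seed); rerunning with the same seed
    reproduces the report exactly.
    """
    timings: dict[str, float] = {}
    t_all = time.time()
    sim_cfg = config.simulation
    conditions = list(sim_cfg.conditions)
    sensor_roi, brain_roi = config.resolved_rois()

    current = {"stage": "init"}

    def stage(name):
        logger.info("stage: %s", name)
        current["stage"] = name
        timings[name] = time.time()
        return name

    try:
        stage("simulate")
        if dataset is None:
            sim_cfg = dataclasses.replace(sim_cfg, seed=config.seed)
            dataset, truth = generate_dataset(sim_cfg)
        else:
            truth = dataset.ground_truth
        timings["simulate"] = time.time() - timings["simulate"]

        stage("preprocess")
        if config.preprocess:
            dataset = dataset.map_recordings(
                lambda r: preprocess_recording(r, artifact_span=sim_cfg.artifact.span)
            )
        timings["preprocess"] = time.time() - timings["preprocess"]

        stage("tfr")
        roi_maps: dict[str, dict[tuple[str, str], ZSpectrogram]] = {"sensor": {}, "brain": {}}
        for key, rec in dataset.recordings.items():
            zmap = _roi_zmap(rec, sorted(set(sensor_roi) | set(brain_roi)), config)
            names = zmap.channel_names or []
            for roi_name, roi in (("sensor", sensor_roi), ("brain", brain_roi)):
                idx = [i for i, c in enumerate(names) if c in roi]
                roi_maps[roi_name][key] = ZSpectrogram(
                    values=zmap.values[idx].mean(axis=0),
                    freqs=zmap.freqs,
                    times=zmap.times,
                    dims=(),
                    baseline_window=zmap.baseline_window,
                )
        timings["tfr"] = time.time() - timings["tfr"]

        stage("windows")
        grand = {
            roi: grand_average(list(maps.values())) for roi, maps in roi_maps.items()
        }
        bands = {"alpha": config.alpha_band, "beta": config.beta_band}
        windows: dict[str, ErspWindow | None] = {}
        for name, roi, band, sign, latency in ERSP_DEFS:
            cands = detect_windows(grand[roi], bands[band], config.window_threshold)
            windows[name] = pick_window(cands, sign, latency)
        timings["windows"] = time.time() - timings["windows"]

        stage("measures")
        rows = []
        for (pid, cond), rec in dataset.recordings.items():
            for name, roi, band, sign, _ in ERSP_DEFS:
                win = windows[name]
                zmap = roi_maps[roi][(pid, cond)]
                if win is None:
                    mag, dur = float("nan"), float("nan")
                else:
                    mag = ersp_magnitude(zmap, win)
                    dur = ersp_duration(
                        zmap,
                        bands[band],
                        sign,
                        smooth_window=config.smooth_window,
                        threshold=config.duration_threshold,
                    )
                rows.append(
                    {
                        "participant_id": pid,
                        "group": rec.group,
                        "condition": cond,
                        "measure": name,
                        "band": band,
                        "sign": sign,
                        "magnitude_z": mag,
                        "duration_s": dur,
                    }
                )
        measures = pd.DataFrame(rows)
        timings["measures"] = time.time() - timings["measures"]

        stage("ratings")
        ratings = simulate_ratings(config.ratings, truth, seed=config.seed + 1_000_003)
        timings["ratings"] = time.time() - timings["ratings"]

        stage("stats")
        stats_seed = config.seed + 2_000_003
        ats_out: dict[str, dict] = {}
        posthoc_out: dict[str, dict] = {}
        pairs = [(conditions[0], c) for c in conditions[1:]]
        ats_out["rating"] = _ats_summary(
            ratings.rename(columns={"rating": "y"}), "y", conditions
        )
        ph = posthoc_paired(
            _paired_values(ratings, "rating", conditions), pairs, config.posthoc_method
        )
        posthoc_out["rating"] = {
            "pairs": ["-".join(p) for p in ph.pairs],
            "p_raw": ph.p_raw,
            "p_adjusted": ph.p_adjusted,
            "method": ph.method,
        }
        for name, _, _, _, _ in ERSP_DEFS:
            sub = measures[measures["measure"] == name]
            if sub["magnitude_z"].isna().any():
                continue
            for value, label in (("magnitude_z", "magnitude"), ("duration_s", "duration")):
                key = f"{name}_{label}"
                ats_out[key] = _ats_summary(sub, value, conditions)
                ph = posthoc_paired(
                    _paired_values(sub, value, conditions), pairs, config.posthoc_method
                )
                posthoc_out[key] = {
                    "pairs": ["-".join(p) for p in ph.pairs],
                    "p_raw": ph.p_raw,
                    "p_adjusted": ph.p_adjusted,
                    "method": ph.method,
                }

        clusters_out: dict[str, dict] = {}
        if config.compute_clusters and len(conditions) >= 2:
            pids = dataset.participants
            maps_key = "brain"

            def stack(cond):
                return np.stack([roi_maps[maps_key][(p, cond)].values for p in pids])

            res = cluster_permutation_tfr(
                stack(conditions[0]),
                stack(conditions[1]),
                paired=True,
                cluster_alpha=config.cluster_alpha,
                n_perm=config.n_perm,
                seed=stats_seed,
            )
            clusters_out[f"{conditions[0]}_vs_{conditions[1]}"] = _cluster_summary(
                res, roi_maps[maps_key][(pids[0], conditions[0])]
            )
            hc = [p for p in pids if dataset.group_of(p) == "HC"]
            cp = [p for p in pids if dataset.group_of(p) == "CP"]
            if hc and cp:
                mean_maps = {
                    p: np.mean([roi_maps[maps_key][(p, c)].values for c in conditions], axis=0)
                    for p in pids
                }
                res_g = cluster_permutation_tfr(
                    np.stack([mean_maps[p] for p in hc]),
                    np.stack([mean_maps[p] for p in cp]),
                    paired=False,
                    cluster_alpha=config.cluster_alpha,
                    n_perm=config.n_perm,
                    seed=stats_seed + 1,
                )
                clusters_out["HC_vs_CP"] = _cluster_summary(
                    res_g, roi_maps[maps_key][(pids[0], conditions[0])]
                )

        location_out: dict[str, dict] = {}
        if config.compute_location_maps and windows["beta_ers"] is not None:
            pids = dataset.participants
            loc = {}
            for key, rec in dataset.recordings.items():
                spect = morlet_tfr(
                    rec, freqs=config.tfr_freqs, spec=config.wavelet, decim=config.tfr_decim
                )
                z = zscore_baseline(spect, config.zscore_baseline)
                loc[key] = (
                    ersp_location_map(z, windows["beta_ers"]),
                    rec.channel_names,
                )
            common = set.intersection(*(set(n) for _, n in loc.values()))
            chan_order = [c for c in dataset.recordings[(pids[0], conditions[0])].channel_names if c in common]

            def loc_matrix(cond):
                out = []
                for p in pids:
                    vec, names = loc[(p, cond)]
                    lookup = dict(zip(names, vec))
                    out.append([lookup[c] for c in chan_order])
                return np.array(out)

            if len(conditions) >= 2:
                mt = permutation_ttest_maps(
                    loc_matrix(conditions[0]),
                    loc_matrix(conditions[1]),
                    paired=True,
                    n_perm=config.n_perm,
                    alpha=config.alpha,
                    seed=stats_seed + 2,
                )
                location_out[f"beta_ers_{conditions[0]}_vs_{conditions[1]}"] = {
                    "channels": chan_order,
                    "t": mt.t,
                    "q": mt.q,
                    "significant_channels": [
                        c for c, m in zip(chan_order, mt.mask) if m
                    ],
                }

        psd_out: dict[str, dict] = {}
        if config.compute_psd:
            pids = dataset.participants
            psds = {
                key: baseline_psd(
                    rec,
                    baseline=config.psd_baseline,
                    channels=[c for c in brain_roi if c in rec.channel_names],
                )
                for key, rec in dataset.recordings.items()
            }
            if len(conditions) >= 2:
                cmp_cond = compare_baselines(
                    [psds[(p, conditions[0])] for p in pids],
                    [psds[(p, conditions[1])] for p in pids],
                    paired=True,
                    n_perm=config.n_perm,
                    alpha=config.alpha,
                    seed=stats_seed + 3,
                )
                psd_out[f"{conditions[0]}_vs_{conditions[1]}"] = {
                    "n_significant_bins": int(cmp_cond.mask.sum()),
                    "fraction_significant": float(cmp_cond.mask.mean()),
                }
            hc = [p for p in pids if dataset.group_of(p) == "HC"]
            cp = [p for p in pids if dataset.group_of(p) == "CP"]
            if hc and cp:

                def subj_mean_psd(p):
                    # condition-averaged relative spectrum per subject
                    ref = psds[(p, conditions[0])]
                    return dataclasses.replace(
                        ref,
                        rel_power=np.mean(
                            [psds[(p, c)].rel_power for c in conditions], axis=0
                        ),
                    )

                cmp_grp = compare_baselines(
                    [subj_mean_psd(p) for p in hc],
                    [subj_mean_psd(p) for p in cp],
                    paired=False,
                    n_perm=config.n_perm,
                    alpha=config.alpha,
                    seed=stats_seed + 4,
                )
                psd_out["HC_vs_CP"] = {
                    "n_significant_bins": int(cmp_grp.mask.sum()),
                    "fraction_significant": float(cmp_grp.mask.mean()),
                }

        # Behavioral-neural association: change (first vs second
        # condition) in rating vs change in beta-ERS magnitude.
        correlation: dict[str, float] = {}
        if len(conditions) >= 2 and windows["beta_ers"] is not None:
            rw = _paired_values(ratings, "rating", conditions)
            sub = measures[measures["measure"] == "beta_ers"]
            mw = _paired_values(sub, "magnitude_z", conditions)
            d_rating = rw[conditions[0]] - rw[conditions[1]]
            d_ers = mw[conditions[0]] - mw[conditions[1]]
            try:
                rho, p = spearman(d_rating, d_ers)
                correlation = {"rho": rho, "p": p, "n": int(len(d_rating))}
            except ValueError:
                correlation = {"rho": float("nan"), "p": float("nan"), "n": int(len(d_rating))}
        timings["stats"] = time.time() - timings["stats"]
    except Exception as err:
        raise RuntimeError(f"pipeline stage {current['stage']!r} failed: {err}") from err

    # Mean +- SE (and SD) per group x condition for each scalar output.
    summaries = []
    for name, _, _, _, _ in ERSP_DEFS:
        sub = measures[measures["measure"] == name]
        for value, label in (("magnitude_z", "magnitude"), ("duration_s", "duration")):
            g = sub.groupby(["group", "condition"], sort=False)[value]
            s = g.agg(["mean", "sem", "std"]).reset_index()
            s.insert(0, "measure", f"{name}_{label}")
            summaries.append(s)
    g = ratings.groupby(["group", "condition"], sort=False)["rating"]
    s = g.agg(["mean", "sem", "std"]).reset_index()
    s.insert(0, "measure", "rating")
    summaries.append(s)
    summary = pd.concat(summaries, ignore_index=True)

    win_out = {
        name: (
            None
            if w is None
            else {"band": w.band.name, "sign": w.sign, "t_start": w.t_start, "t_end": w.t_end}
        )
        for name, w in windows.items()
    }
    provenance = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "numpy": np.__version__,
        "timings_s": {k: round(v, 3) for k, v in timings.items() if isinstance(v, float)},
        "total_s": round(time.time() - t_all, 3),
    }
    return RunReport(
        windows=win_out,
        measures=measures,
        ratings=ratings,
        summary=summary,
        ats=ats_out,
        posthoc=posthoc_out,
        clusters=clusters_out,
        psd=psd_out,
        correlation=correlation,
        location=location_out,
        provenance=provenance,
    )


def _cluster_summary(res, ref_map) -> dict:
    sig = res.significant()
    return {
        "n_clusters": len(res.clusters),
        "n_significant": len(sig),
        "min_p": min((c.p for c in res.clusters), default=1.0),
        "masses": [c.mass for c in res.clusters[:5]],
        "p_values": [c.p for c in res.clusters[:5]],
        "n_permutations": res.n_permutations,
    }
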