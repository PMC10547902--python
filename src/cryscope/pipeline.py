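"""End-to-end orchestration: synthetic session -> features -> statistics.

``run_all`` generates (or loads) one multimodal session, runs every
analysis stage, merges the per-episode feature table and writes a
report bundle (CSV tables + a JSON report with provenance).  Each
stage logs its in/out counts; a failure aborts with a stage-named
error.
"""
from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, EEG_CHANNELS
from . import simulate, cry_acoustics, eeg_power, nirs_clean, comfort_scale
from . import integrate_stats, distress_classifier

log = logging.getLogger("cryscope")

ACOUSTIC_FEATURES = [
    "f0_mean", "f0_min", "f0_max", "f0_sd", "f1", "f2", "f3",
    "high_pitch_pct", "hyperphonation_pct", "jitter_local", "shimmer_local",
    "hnr", "cryCE", "unvoicedCE", "cryCE_pct", "unvoicedCE_pct",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage tag
                raise StageError(name, exc) from exc
        return wrapper
    return deco


# ---------------------------------------------------------------------------
# per-modality stages


@_stage("acoustics")
def acoustics_stage(audio, fs, annotations, cfg) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-unit and per-episode acoustic feature tables.

    Each annotated cry/distress interval is treated as one cry episode;
    units are re-detected inside it and analysed individually, and the
    episode row carries the unit means plus the time-domain features.
    """
    unit_rows, episode_rows = [], []
    ep_id = 0
    for start, end, label in annotations:
        if label == "resting":
            continue
        i0, i1 = int(round(start * fs)), int(round(end * fs))
        segment = audio[i0:i1]
        episodes = cry_acoustics.detect_voiced_regions(segment, fs, cfg.acoustics, condition=label)
        units, gaps = [], []
        for ep in episodes:
            units.extend(ep.units)
            gaps.extend(ep.unvoiced_intervals)
        if not units:
            log.warning("acoustics: no units detected in %s episode at %.1fs", label, start)
            continue
        merged = cry_acoustics.CryEpisode(units, gaps, condition=label)
        tf = cry_acoustics.time_features(merged)
        feats = []
        for u in units:
            x = segment[int(u.start * fs) : int(u.end * fs)]
            fv = cry_acoustics.analyze_unit(x, fs, cfg.acoustics)
            row = {k: getattr(fv, k) for k in (
                "f0_mean", "f0_min", "f0_max", "f0_sd", "f1", "f2", "f3",
                "high_pitch_pct", "hyperphonation_pct",
                "jitter_local", "shimmer_local", "hnr")}
            row.update(episode_id=ep_id, condition=label,
                       start_s=start + u.start, end_s=start + u.end, valid=fv.valid)
            unit_rows.append(row)
            if fv.valid:
                feats.append(row)
        ep_row = {"episode_id": ep_id, "condition": label,
                  "start_s": start, "end_s": end,
                  "cryCE": tf.cryCE, "unvoicedCE": tf.unvoicedCE,
                  "cryCE_pct": tf.cryCE_pct, "unvoicedCE_pct": tf.unvoicedCE_pct,
                  "n_units": len(units)}
        if feats:
            fdf = pd.DataFrame(feats)
            for c in ("f0_mean", "f0_min", "f0_max", "f0_sd", "f1", "f2", "f3",
                      "high_pitch_pct", "hyperphonation_pct",
                      "jitter_local", "shimmer_local", "hnr"):
                ep_row[c] = float(fdf[c].mean())
        episode_rows.append(ep_row)
        ep_id += 1
    log.info("acoustics: %d units in %d episodes", len(unit_rows), len(episode_rows))
    return pd.DataFrame(unit_rows), pd.DataFrame(episode_rows)


@_stage("eeg")
def eeg_stage(eeg_data, fs, annotations, cfg) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Band-power table, percent change vs resting, and epoch counts."""
    rec = eeg_power.EEGRecording(eeg_data, fs)
    bad = eeg_power.detect_bad_channels(rec, cfg.eeg)
    rec.bad_channels = bad
    info = {"bad_channels": sorted(bad)}
    if len(bad) == 1:
        rec = eeg_power.interpolate_spherical_spline(rec, next(iter(bad)), cfg.eeg)
        info["interpolated"] = info["bad_channels"]
    elif len(bad) > cfg.eeg.max_interpolated_channels:
        raise ValueError(f"{len(bad)} bad channels (max 1 interpolated): {sorted(bad)}")
    rec = eeg_power.preprocess(rec, cfg.eeg)
    epochs = eeg_power.epoch_and_reject(rec, annotations, cfg.eeg)
    info["n_epochs"] = len(epochs)
    info["n_rejected"] = sum(e.quality == "rejected" for e in epochs)
    table = eeg_power.band_power_table(epochs, fs, cfg.eeg)
    rest = table[table["condition"] == "resting"]
    frames = []
    for cond in ("cry", "distress"):
        sub = table[table["condition"] == cond]
        if len(sub) and len(rest):
            pc = eeg_power.percent_change(sub, rest)
            pc["condition"] = cond
            frames.append(pc)
    pchange = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    log.info("eeg: %d epochs (%d rejected), bad=%s", info["n_epochs"],
             info["n_rejected"], info["bad_channels"])
    return table, pchange, info


@_stage("nirs")
def nirs_stage(nirs_df, annotations, cfg) -> pd.DataFrame:
    cleaned = nirs_clean.clean(nirs_df, cfg.nirs)
    segments = nirs_clean.segment(cleaned, annotations, cfg.nirs)
    table = nirs_clean.segment_table(segments, cfg.nirs)
    log.info("nirs: %d segments, %d variable exclusions",
             len(segments), int((~table["keep"]).sum()))
    return table


@_stage("comfort")
def comfort_stage(comfort_df) -> pd.DataFrame:
    table = comfort_scale.score_table(comfort_df)
    log.info("comfort: %d records (%d valid)", len(table), int(table["valid"].sum()))
    return table


@_stage("merge")
def build_feature_table(episode_feats, eeg_table, nirs_table, comfort_table,
                        annotations) -> pd.DataFrame:
    """One row per cry/distress episode with all modality features.

    EEG relative power is averaged over the epochs inside the episode's
    interval (one column per band x channel and a channel-mean column
    per band); NIRS means come from the episode's segment; COMFORT
    items and total join on episode id.
    """
    if episode_feats.empty:
        return pd.DataFrame()
    rows = []
    for _, ep in episode_feats.iterrows():
        row = dict(ep)
        m = (eeg_table["start_s"] >= ep["start_s"]) & (eeg_table["start_s"] < ep["end_s"])
        sub = eeg_table[m]
        for band in ("delta", "theta", "alpha"):
            bsub = sub[sub["band"] == band]
            for ch in EEG_CHANNELS:
                vals = bsub[bsub["channel"] == ch]["relative_power"]
                row[f"eeg_{band}_{ch}"] = float(vals.mean()) if len(vals) else np.nan
            row[f"eeg_{band}"] = float(bsub["relative_power"].mean()) if len(bsub) else np.nan
        nsub = nirs_table[(nirs_table["start_s"] == ep["start_s"])
                          & (nirs_table["condition"] == ep["condition"])]
        for var in nirs_clean.VARIABLES:
            v = nsub[(nsub["variable"] == var) & nsub["keep"]]["mean"]
            row[var] = float(v.iloc[0]) if len(v) else np.nan
        csub = comfort_table[comfort_table["episode_id"] == ep["episode_id"]]
        if len(csub) and bool(csub["valid"].iloc[0]):
            for item in comfort_scale.ITEMS + ("total",):
                row[f"comfort_{item}"] = float(csub[item].iloc[0])
        rows.append(row)
    return pd.DataFrame(rows)


@_stage("integrate")
def integrate_stage(feature_table, eeg_table, cfg, seed) -> dict:
    """Spearman matrix, concordance report and condition comparisons."""
    out = {}
    if feature_table.empty:
        return out
    numeric = feature_table.select_dtypes(include=[np.number]).drop(
        columns=["episode_id"], errors="ignore")
    numeric = numeric.loc[:, numeric.notna().any()]
    rho, pval = integrate_stats.spearman_matrix(numeric)
    out["spearman_rho"] = rho
    out["spearman_p"] = pval

    audio = [c for c in ACOUSTIC_FEATURES if c in numeric.columns]
    partners = [c for c in numeric.columns
                if c.startswith(("eeg_", "comfort_")) or c in nirs_clean.VARIABLES]
    tables = {cond: feature_table[feature_table["condition"] == cond]
              for cond in ("cry", "distress")}
    tables = {k: v for k, v in tables.items() if len(v) >= 3}
    if tables:
        out["concordance"] = integrate_stats.concordance_report(
            tables, audio, partners, cfg.stats)

    # EEG band power comparisons across the three conditions
    comparisons = []
    for band in ("delta", "theta", "alpha"):
        groups = {}
        for cond in ("resting", "cry", "distress"):
            vals = eeg_table[(eeg_table["condition"] == cond)
                             & (eeg_table["band"] == band)]["relative_power"].to_numpy()
            if len(vals) >= 2:
                groups[cond] = vals
        if len(groups) == 3:
            balanced = integrate_stats.balanced_subsample(groups, seed)
            omni, posthoc = integrate_stats.kruskal_dunn(balanced)
            comparisons.append({"feature": f"eeg_{band}", "method": omni.method,
                                "statistic": omni.statistic, "p": omni.p_value})
            comparisons.extend({
                "feature": f"eeg_{band}", "method": "dunn",
                "pair": "-".join(r.extra["pair"]), "statistic": r.statistic,
                "p": r.p_value, "p_adj": r.p_adjusted,
            } for r in posthoc)
    out["comparisons"] = pd.DataFrame(comparisons)
    return out


@_stage("classify")
def classify_stage(cfg, seed) -> dict:
    """Train and evaluate the distress classifiers on synthetic units."""
    if cfg.classifier == "none":
        return {"skipped": True}
    waves, labels = simulate.synth_unit_dataset(cfg.classifier_n_units, seed)
    split = distress_classifier.make_split(len(labels), cfg.classify.frac_train, seed)
    reports = {"n_units": len(labels),
               "n_train": len(split.train), "n_validation": len(split.validation)}
    if cfg.classifier in ("rf", "both"):
        feats = np.stack([cry_acoustics.mfcc(w, simulate.AUDIO_FS, cfg.acoustics)
                          for w in waves])
        ds = distress_classifier.LabeledDataset(feats, labels, split)
        rf = distress_classifier.train_rf(ds, seed, cfg.classify)
        reports["rf"] = distress_classifier.evaluate(rf, ds).as_dict()
    if cfg.classifier in ("cnn", "both"):
        imgs = np.stack([cry_acoustics.spectrogram(w, simulate.AUDIO_FS, cfg.acoustics)
                         for w in waves])
        ds = distress_classifier.LabeledDataset(imgs, labels, split)
        cnn = distress_classifier.train_cnn(ds, seed, cfg=cfg.classify)
        reports["cnn"] = distress_classifier.evaluate(cnn, ds).as_dict()
    log.info("classify: %s", {k: v for k, v in reports.items() if k in ("rf", "cnn")})
    return reports


# ---------------------------------------------------------------------------
# run-all


def run_all(cfg: RunConfig | None = None, write: bool = True) -> dict:
    """Synthetic session -> full analysis -> report bundle."""
    cfg = cfg or RunConfig()
    out_dir = Path(cfg.out_dir)
    session = simulate.synth_session(cfg.seed, sim=cfg.simulate)
    ann = session.annotations

    units, episodes = acoustics_stage(session.audio, session.fs, ann, cfg)
    eeg_table, eeg_pchange, eeg_info = eeg_stage(session.eeg, session.eeg_fs, ann, cfg)
    nirs_table = nirs_stage(session.nirs, ann, cfg)
    comfort_table = comfort_stage(session.comfort)
    features = build_feature_table(episodes, eeg_table, nirs_table, comfort_table, ann)
    stats_out = integrate_stage(features, eeg_table, cfg, cfg.seed)
    classifier_out = classify_stage(cfg, cfg.seed)

    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    report = {
        "provenance": {
            "package_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "seed": cfg.seed,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        },
        "session": {
            "duration_s": session.duration_s,
            "n_annotations": len(ann),
            "n_cry_episodes": sum(1 for *_, lab in ann if lab == "cry"),
            "n_distress_episodes": sum(1 for *_, lab in ann if lab == "distress"),
        },
        "counts": {
            "units": int(len(units)), "episodes": int(len(episodes)),
            **{f"eeg_{k}": v for k, v in eeg_info.items()},
            "nirs_segments": int(nirs_table["segment"].nunique()) if len(nirs_table) else 0,
            "comfort_records": int(len(comfort_table)),
        },
        "classifier": classifier_out,
    }
    artifacts = {
        "session": session, "units": units, "episodes": episodes,
        "eeg_table": eeg_table, "eeg_percent_change": eeg_pchange,
        "nirs_table": nirs_table, "comfort_table": comfort_table,
        "feature_table": features, "stats": stats_out, "report": report,
    }
    if write:
        out_dir.mkdir(parents=True, exist_ok=True)
        session.to_dir(out_dir / "session")
        units.to_csv(out_dir / "unit_features.csv", index=False)
        episodes.to_csv(out_dir / "episode_features.csv", index=False)
        eeg_table.to_csv(out_dir / "eeg_power.csv", index=False)
        eeg_pchange.to_csv(out_dir / "eeg_percent_change.csv", index=False)
        nirs_table.to_csv(out_dir / "nirs_segments.csv", index=False)
        comfort_table.to_csv(out_dir / "comfort.csv", index=False)
        features.to_csv(out_dir / "feature_table.csv", index=False)
        if "spearman_rho" in stats_out:
            stats_out["spearman_rho"].to_csv(out_dir / "spearman_rho.csv")
            stats_out["spearman_p"].to_csv(out_dir / "spearman_p.csv")
        if "concordance" in stats_out:
            stats_out["concordance"].to_csv(out_dir / "concordance.csv", index=False)
        if "comparisons" in stats_out and len(stats_out["comparisons"]):
            stats_out["comparisons"].to_csv(out_dir / "comparisons.csv", index=False)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=str)
        cfg.save(out_dir / "config.yaml")
    return artifacts
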