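"""End-to-end study processing: signals in, effect tables out.

One subject's data comprises a 2000 Hz contact-PPG record per contact site,
a 25 Hz raw iPPG trace per head site (either extracted from video frames or
consumed directly), and a beat-wise reference series.  Per (subject, site,
interval) the pipeline bandpasses the record, extracts the 10 s analysis
window, detects and segments beats, quality-filters the segments, builds a
template, fits the Gamma-Gaussian decomposition, and measures the four
morphological features.  Subjects for whom any template fails, or whose
reference series is missing, are excluded from all analyses; the statistics
layer then runs per site and feature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import beats as B
from . import ippg as I
from . import pwd as P
from . import stats as S
from .signals import SampledSignal, read_signal, write_signal
from .synthgen import (CONTACT_SITES, StudyConfig, StudyData,
                       generate_study, generate_video)

__all__ = ["process_record", "process_subject", "run_study",
           "StudyResult", "export_study", "ingest_study"]

EXCLUDE_NO_TEMPLATE = "no-template-in-interval"
EXCLUDE_MISSING_REFERENCE = "missing-reference"


@dataclass
class StudyResult:
    table: pd.DataFrame          # long: subject, site, interval, feature, value
    reference: pd.DataFrame      # long reference values per interval
    anova: pd.DataFrame
    effects: pd.DataFrame
    ref_anova: pd.DataFrame
    ref_effects: pd.DataFrame
    qc: pd.DataFrame             # per-template QC rows
    excluded: dict               # subject -> reason
    manifest: dict = field(default_factory=dict)


def to_contact_convention(raw: SampledSignal,
                          target_fs: float = 2000.0) -> SampledSignal:
    """Raw iPPG trace (camera polarity) -> contact-PPG convention."""
    return I.invert_and_resample(raw, target_fs=target_fs)


def process_record(record: SampledSignal, t_cpt: float,
                   *, fit_seed: int = 0) -> tuple[dict, list[dict]]:
    """All three analysis windows of one filtered-ready record.

    Returns (features_by_interval, qc_rows); raises
    :class:`~coldwave.beats.NoTemplateError` /
    :class:`~coldwave.beats.NoBeatsError` when any window yields no
    template, which callers map to subject exclusion.
    """
    filtered = B.bandpass(record)
    out: dict[str, P.MorphFeatures] = {}
    qc_rows = []
    for interval, start in B.interval_starts(t_cpt).items():
        window = B.extract_interval(filtered, start)
        template = B.make_template(window)
        params, features, qc = P.template_to_features(
            template, seed=fit_seed)
        out[interval] = features
        qc_rows.append({"interval": interval, **qc,
                        "median_bbi": template.median_bbi,
                        **{f"param_{k}": getattr(params, k) for k in
                           ("s1", "alpha1", "beta1", "a2", "mu2", "sigma2")}})
    return out, qc_rows


def process_subject(subject_id: str, signals: dict, reference, t_cpt: float,
                    *, fit_seed: int = 0):
    """Feature rows for one subject, or (None, reason, qc) on exclusion."""
    rows, qc_rows = [], []
    for site, sig in signals.items():
        record = sig
        if sig.meta.get("kind") in ("ippg_raw", "ippg") and sig.fs < 200:
            record = to_contact_convention(sig)
        try:
            feats, qcs = process_record(record, t_cpt, fit_seed=fit_seed)
        except (B.NoBeatsError, B.NoTemplateError, P.FitError) as exc:
            return None, f"{EXCLUDE_NO_TEMPLATE}: {site}: {exc}", qc_rows
        for interval, f in feats.items():
            for name, value in f.as_dict().items():
                rows.append({"subject": subject_id, "site": site,
                             "interval": interval, "feature": name,
                             "value": value})
        for q in qcs:
            qc_rows.append({"subject": subject_id, "site": site, **q})
    if reference is None or len(reference) == 0:
        return None, EXCLUDE_MISSING_REFERENCE, qc_rows
    ref_rows = []
    for interval, start in B.interval_starts(t_cpt).items():
        scalars = S.interval_reference(reference, start)
        if any(np.isnan(v) for v in scalars.values()):
            return None, EXCLUDE_MISSING_REFERENCE, qc_rows
        for name, value in scalars.items():
            ref_rows.append({"subject": subject_id, "site": "reference",
                             "interval": interval, "feature": name,
                             "value": value})
    return (rows, ref_rows), None, qc_rows


def run_study(study: StudyData, *, render_video: bool = False,
              video_frame_shape: tuple[int, int] = (48, 64),
              video_pixel_noise_sd: float = 2.0,
              seed: int = 0) -> StudyResult:
    """Process a generated study end to end.

    With ``render_video`` the head-site traces are first embedded into
    synthetic frames and re-extracted through the imaging-PPG path
    (smoothing, ROI averaging, inversion, resampling); otherwise the traces
    enter the pipeline directly in camera polarity.
    """
    config = study.config
    rng = np.random.default_rng([seed % 2**31, 99])
    feature_rows, reference_rows, qc_rows = [], [], []
    excluded: dict[str, str] = {}
    polygon = _default_roi(video_frame_shape)
    for sub in study.subjects:
        missing_sites = [s for s in config.sites if s not in sub.signals]
        if missing_sites:
            excluded[sub.subject] = (
                f"{EXCLUDE_NO_TEMPLATE}: missing signals for "
                f"{', '.join(missing_sites)}")
            continue
        signals = {}
        for site, sig in sub.signals.items():
            # low-rate traces are video-derived iPPG; contact records pass
            # through untouched
            if sig.fs < config.fs_contact / 2:
                if render_video:
                    frames = generate_video(
                        sig, video_frame_shape, polygon,
                        video_pixel_noise_sd, config.fps_video, rng)
                    raw = I.extract_roi_signal(frames, polygon)
                else:
                    raw = sig.with_values(-sig.values)
                    raw = SampledSignal(raw.values, raw.fs, raw.t0,
                                        {**sig.meta, "kind": "ippg_raw"})
                signals[site] = raw
            else:
                signals[site] = sig
        result, reason, qcs = process_subject(
            sub.subject, signals, sub.reference, config.t_cpt,
            fit_seed=seed)
        qc_rows.extend(qcs)
        if result is None:
            excluded[sub.subject] = reason
            continue
        rows, ref_rows = result
        feature_rows.extend(rows)
        reference_rows.extend(ref_rows)

    table = pd.DataFrame(feature_rows)
    reference = pd.DataFrame(reference_rows)
    if len(table):
        anova, effects = S.analyze_study(table)
    else:
        anova = effects = pd.DataFrame()
    if len(reference):
        ref_anova, ref_effects = S.analyze_study(reference)
    else:
        ref_anova = ref_effects = pd.DataFrame()
    manifest = {
        "n_subjects": config.n_subjects,
        "n_analyzed": int(table["subject"].nunique()) if len(table) else 0,
        "n_excluded": len(excluded),
        "exclusions": excluded,
        "sites": list(config.sites),
        "seed": seed,
        "templates_attempted": config.n_subjects * len(config.sites) * 3,
        "templates_built": len(qc_rows),
        "render_video": render_video,
        # repeated measures need >= 3 complete subjects per (site, feature)
        "stats": "ok" if len(anova) else "insufficient-n",
    }
    return StudyResult(table=table, reference=reference, anova=anova,
                       effects=effects, ref_anova=ref_anova,
                       ref_effects=ref_effects,
                       qc=pd.DataFrame(qc_rows), excluded=excluded,
                       manifest=manifest)


def _default_roi(frame_shape: tuple[int, int]) -> I.RoiPolygon:
    """A rectangular ROI with margin inside the frame."""
    h, w = frame_shape
    m_y, m_x = max(2, h // 6), max(2, w // 6)
    return I.RoiPolygon(vertices=[[m_x, m_y], [w - m_x, m_y],
                                  [w - m_x, h - m_y], [m_x, h - m_y]],
                        label="forehead")


# ---------------------------------------------------------------------------
# Export / ingest (round-trippable plain-text formats)
# ---------------------------------------------------------------------------

def export_study(study: StudyData, out_dir: Path | str) -> Path:
    """Write a generated study as per-subject CSV signals with YAML
    sidecars, reference CSVs and the ground-truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = study.config
    config.to_yaml(out / "config.yaml")
    for sub in study.subjects:
        d = out / sub.subject
        d.mkdir(exist_ok=True)
        for site, sig in sub.signals.items():
            kind = "ppg" if site in CONTACT_SITES else "ippg_source"
            meta = {**sig.meta, "site": site, "kind": kind,
                    "t_cpt": float(config.t_cpt)}
            write_signal(SampledSignal(sig.values, sig.fs, sig.t0, meta),
                         d / site)
        sub.reference.to_csv(d / "reference.csv", index=False)
    study.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    return out


def ingest_study(data_dir: Path | str) -> StudyData:
    """Load a study previously written by :func:`export_study`."""
    from .synthgen import SubjectData

    data_dir = Path(data_dir)
    cfg_path = data_dir / "config.yaml"
    if not cfg_path.exists():
        raise FileNotFoundError(f"no config.yaml under {data_dir}")
    config = StudyConfig.from_yaml(cfg_path)
    subjects = []
    subject_dirs = sorted(p for p in data_dir.iterdir() if p.is_dir())
    if not subject_dirs:
        raise FileNotFoundError(f"no subject directories under {data_dir}")
    for d in subject_dirs:
        signals = {}
        for site in config.sites:
            csv = d / f"{site}.csv"
            if csv.exists():
                signals[site] = read_signal(d / site)
        ref_path = d / "reference.csv"
        reference = pd.read_csv(ref_path) if ref_path.exists() else None
        subjects.append(SubjectData(subject=d.name, signals=signals,
                                    onsets={}, reference=reference,
                                    params={}))
    gt_path = data_dir / "ground_truth.csv"
    gt = pd.read_csv(gt_path) if gt_path.exists() else pd.DataFrame()
    return StudyData(config=config, subjects=subjects, ground_truth=gt)


def write_results(result: StudyResult, out_dir: Path | str) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(out / "features.csv", index=False)
    result.reference.to_csv(out / "reference_intervals.csv", index=False)
    result.anova.to_csv(out / "anova.csv", index=False)
    result.effects.to_csv(out / "effects.csv", index=False)
    result.ref_anova.to_csv(out / "reference_anova.csv", index=False)
    result.ref_effects.to_csv(out / "reference_effects.csv", index=False)
    result.qc.to_csv(out / "qc.csv", index=False)
    outlier_rows = []
    for (site, feature, interval), grp in result.table.groupby(
            ["site", "feature", "interval"]):
        if len(grp) >= 4:
            outlier_rows.append({
                "site": site, "feature": feature, "interval": interval,
                "n_outliers": S.count_outliers(grp["value"].to_numpy())})
    pd.DataFrame(outlier_rows).to_csv(out / "outliers.csv", index=False)
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True))
    return out
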