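"""End-to-end orchestration: EEG segments -> functional networks -> BNI/NI ->
group comparison reports.

Per subject, each artifact-free segment is preprocessed, its functional
network inferred, the network's robust BNI_hat computed, K calibrated to
BNI_pre = 0.5 and node ictogenicity evaluated; the subject-level profile is
the mean over segments.  The group layer then runs three separate test
families with Holm correction inside each: the one-sided BNI_hat comparison
(m = 1), the one-sided occipital NI comparisons O1/O2 (m = 2), and the
exploratory two-sided comparisons of the 18 remaining nodes (m = 18),
followed by ROC metrics for NI(O2) and the supplementary relative-power and
connectivity-strength comparisons.
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ictogenicity import (
    IctogenicityProfile,
    bni_hat,
    calibrate_K,
    node_ictogenicity,
)
from .networks import FunctionalNetwork, build_network
from .preprocess import preprocess_segment, rereference_average, downsample
from .segment import OCCIPITAL_CHANNELS, EEGSegment
from .stats import (
    bootstrap_median_diff,
    holm,
    node_strength,
    ranksum,
    relative_band_power,
    roc_metrics,
)
from .synthetic import SubjectData
from .theta import ThetaModelParams

logger = logging.getLogger("ictonet")

__all__ = ["AnalysisConfig", "run_subject", "run_cohort"]


@dataclass
class AnalysisConfig:
    """All pipeline parameters; defaults are the canonical analysis values.

    The ``fast()`` profile shrinks the simulation sizes (steps, grid,
    repetitions, surrogate count) for smoke runs and continuous testing; it
    does not change the scientific conventions.
    """

    # preprocessing
    target_fs: float = 250.0
    band: tuple[float, float] = (6.0, 9.0)
    filter_order: int = 4
    # network inference
    n_surrogates: int = 99
    n_iterations: int = 10
    level: float = 0.95
    # simulator
    i0: float = -1.2
    noise_sd: float = 0.6
    dt: float = 0.01
    n_steps: int = 4_000_000
    k1: float = 1.0
    k2: float = 40.0
    n_grid: int = 40
    n_reps_curve: int = 2
    n_reps_ni: int = 4
    n_scan: int = 9
    bni_target: float = 0.5
    bni_tol: float = 0.05
    # statistics
    n_boot: int = 5000
    # bookkeeping
    seed: int = 0
    out_dir: str | None = None

    def theta_params(self) -> ThetaModelParams:
        return ThetaModelParams(
            i0=self.i0, noise_sd=self.noise_sd, dt=self.dt, n_steps=self.n_steps
        )

    @classmethod
    def fast(cls, **overrides) -> "AnalysisConfig":
        """Reduced-size profile for smoke tests and CI."""
        defaults = dict(
            n_surrogates=19, n_steps=20_000, n_grid=8, n_scan=5,
            n_reps_curve=1, n_reps_ni=2, n_boot=500,
        )
        defaults.update(overrides)
        return cls(**defaults)


def _subject_seed(root: int, subject_id: str) -> int:
    h = sum(ord(c) * (i + 1) for i, c in enumerate(subject_id))
    return int(
        np.random.SeedSequence(entropy=root % (2**31), spawn_key=(h,))
        .generate_state(1)[0] % (2**31)
    )


def run_subject(
    segments: list[EEGSegment],
    config: AnalysisConfig,
    subject_id: str = "",
    group: str = "",
    preprocessed: bool = False,
    ni_nodes: list[str] | None = None,
) -> IctogenicityProfile | None:
    """Full per-subject analysis; returns the mean profile over segments.

    Segments whose network cannot be calibrated (e.g. empty networks) are
    skipped with a log entry; returns ``None`` when no segment succeeds.
    """
    seed = _subject_seed(config.seed, subject_id or "anon")
    params = config.theta_params()
    hats, k_stars, nis = [], [], []
    for si, seg in enumerate(segments):
        t0 = time.time()
        try:
            pseg = seg if preprocessed else preprocess_segment(
                seg, config.target_fs, config.band, config.filter_order
            )
            net = build_network(
                pseg,
                n_surrogates=config.n_surrogates,
                n_iterations=config.n_iterations,
                seed=seed + si,
                band=config.band,
                filter_order=config.filter_order,
                level=config.level,
            )
            hat = bni_hat(
                net, params, k1=config.k1, k2=config.k2,
                n_grid=config.n_grid, n_reps=config.n_reps_curve,
                seed=seed + si,
            )
            k_star = calibrate_K(
                net, params, target=config.bni_target, tol=config.bni_tol,
                k1=config.k1, k2=config.k2, n_scan=config.n_scan,
                n_reps=config.n_reps_ni, seed=seed + si,
            )
            ni = node_ictogenicity(
                net, k_star, params, n_reps=config.n_reps_ni,
                nodes=ni_nodes, seed=seed + si,
            )
        except (RuntimeError, ValueError) as exc:
            logger.warning(
                "subject=%s segment=%s stage=failed error=%s",
                subject_id, getattr(seg, "segment_id", si), exc,
            )
            continue
        logger.info(
            "subject=%s segment=%s stage=done seed=%d elapsed=%.1fs",
            subject_id, getattr(seg, "segment_id", si), seed + si,
            time.time() - t0,
        )
        hats.append(hat)
        k_stars.append(k_star)
        nis.append(ni)
    if not hats:
        logger.warning("subject=%s excluded: no segment succeeded", subject_id)
        return None
    return IctogenicityProfile(
        bni_hat=float(np.mean(hats)),
        k_star=float(np.mean(k_stars)),
        ni=pd.concat(nis, axis=1).mean(axis=1),
        bni_pre=config.bni_target,
        subject_id=subject_id,
        group=group,
    )


def _group_values(df: pd.DataFrame, col: str) -> tuple[np.ndarray, np.ndarray]:
    a = df.loc[df["group"] == "PPR", col].to_numpy()
    b = df.loc[df["group"] == "nonPPR", col].to_numpy()
    return a, b


def run_cohort(
    cohort: list[SubjectData],
    config: AnalysisConfig,
    ni_nodes: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Analyze a full two-group cohort and assemble the report tables.

    Returns a dict of DataFrames: ``profiles`` (one row per subject),
    ``bni_test``, ``occipital_tests``, ``node_tests`` (Table-3 style),
    ``roc`` and ``supplementary`` (Table-4 style).  When
    ``config.out_dir`` is set each table is also written as CSV.
    """
    groups = {s.group for s in cohort}
    if not {"PPR", "nonPPR"} <= groups:
        raise ValueError(f"cohort must contain both groups, got {sorted(groups)}")

    rows = []
    for subj in cohort:
        prof = run_subject(
            subj.segments, config, subject_id=subj.subject_id,
            group=subj.group, ni_nodes=ni_nodes,
        )
        if prof is None:
            continue
        row = {
            "subject_id": prof.subject_id,
            "group": prof.group,
            "bni_hat_mean": prof.bni_hat,
            "k_star_mean": prof.k_star,
        }
        for ch, val in prof.ni.items():
            row[f"NI_{ch}"] = val
        rows.append(row)
    profiles = pd.DataFrame(rows)
    if profiles.empty or profiles["group"].nunique() < 2:
        raise ValueError("fewer than two groups survived the analysis")
    counts = profiles["group"].value_counts()
    if counts.min() < 2:
        raise ValueError(
            "group comparison needs at least 2 surviving subjects per group; "
            f"got {counts.to_dict()}"
        )

    reports: dict[str, pd.DataFrame] = {"profiles": profiles}

    # family 1: one-sided BNI_hat comparison (m = 1)
    a, b = _group_values(profiles, "bni_hat_mean")
    res = ranksum(a, b, tail="right")
    eff = bootstrap_median_diff(a, b, n_boot=config.n_boot, seed=config.seed)
    reports["bni_test"] = pd.DataFrame(
        [{
            "measure": "bni_hat", "p": res.p, "p_corrected": res.p,
            "U": res.W, "z": res.z, "effect_size": eff.median_diff,
            "ci_low": eff.ci_low, "ci_high": eff.ci_high,
        }]
    )

    ni_cols = [c for c in profiles.columns if c.startswith("NI_")]
    have = [c.removeprefix("NI_") for c in ni_cols]

    # family 2: one-sided occipital NI (m = 2)
    occ = [c for c in OCCIPITAL_CHANNELS if c in have]
    occ_rows = []
    for ch in occ:
        a, b = _group_values(profiles, f"NI_{ch}")
        r = ranksum(a, b, tail="right")
        e = bootstrap_median_diff(a, b, n_boot=config.n_boot, seed=config.seed)
        occ_rows.append({
            "node": ch, "p": r.p, "U": r.W, "z": r.z,
            "effect_size": e.median_diff, "ci_low": e.ci_low,
            "ci_high": e.ci_high,
        })
    occ_df = pd.DataFrame(occ_rows)
    if not occ_df.empty:
        occ_df.insert(2, "p_corrected", holm(occ_df["p"].to_numpy()))
    reports["occipital_tests"] = occ_df

    # family 3: exploratory two-sided scan of the remaining nodes (m = 18)
    other = [ch for ch in have if ch not in OCCIPITAL_CHANNELS]
    node_rows = []
    for ch in other:
        a, b = _group_values(profiles, f"NI_{ch}")
        r = ranksum(a, b, tail="two-sided")
        e = bootstrap_median_diff(a, b, n_boot=config.n_boot, seed=config.seed)
        node_rows.append({
            "node": ch, "p": r.p, "U": r.W, "z": r.z,
            "effect_size": e.median_diff, "ci_low": e.ci_low,
            "ci_high": e.ci_high,
        })
    node_df = pd.DataFrame(node_rows)
    if not node_df.empty:
        node_df.insert(2, "p_corrected", holm(node_df["p"].to_numpy()))
    reports["node_tests"] = node_df

    # ROC for NI(O2)
    if "NI_O2" in profiles.columns:
        roc = roc_metrics(
            profiles["NI_O2"].to_numpy(),
            (profiles["group"] == "PPR").to_numpy(),
        )
        reports["roc"] = pd.DataFrame(
            [{
                "measure": "NI_O2", "auc": roc.auc,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
                "threshold": roc.threshold,
            }]
        )

    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        for name, df in reports.items():
            df.to_csv(os.path.join(config.out_dir, f"{name}.csv"), index=False)
    return reports


def occipital_ni_by_subject(
    cohort: list[SubjectData],
    config: AnalysisConfig,
    sim_seed: int = 0,
) -> pd.DataFrame:
    """Per-subject mean occipital NI with simulation seeds shared across
    subjects.

    Calibration and node-removal simulations reuse one seed stream derived
    from ``sim_seed`` for every segment, so Monte-Carlo error is common
    across subjects and cancels in rank-based group comparisons (a paired
    variance-reduction design; the networks themselves still differ).
    Subjects whose segments all fail calibration are dropped.
    """
    from .networks import build_network as _build

    params = config.theta_params()
    rows = []
    for subj in cohort:
        vals = []
        for si, seg in enumerate(subj.segments):
            try:
                pseg = preprocess_segment(
                    seg, config.target_fs, config.band, config.filter_order
                )
                net = _build(
                    pseg, n_surrogates=config.n_surrogates,
                    n_iterations=config.n_iterations,
                    seed=_subject_seed(config.seed, subj.subject_id) + si,
                    band=config.band, filter_order=config.filter_order,
                    level=config.level,
                )
                k_star = calibrate_K(
                    net, params, target=config.bni_target, tol=config.bni_tol,
                    k1=config.k1, k2=config.k2, n_scan=config.n_scan,
                    n_reps=config.n_reps_ni, seed=sim_seed,
                )
                ni = node_ictogenicity(
                    net, k_star, params, n_reps=config.n_reps_ni,
                    nodes=list(OCCIPITAL_CHANNELS), seed=sim_seed,
                )
            except (RuntimeError, ValueError) as exc:
                logger.warning(
                    "subject=%s segment=%s stage=occipital-ni error=%s",
                    subj.subject_id, seg.segment_id, exc,
                )
                continue
            vals.append(ni)
        if not vals:
            continue
        mean_ni = pd.concat(vals, axis=1).mean(axis=1)
        rows.append({
            "subject_id": subj.subject_id, "group": subj.group,
            "NI_O1": mean_ni["O1"], "NI_O2": mean_ni["O2"],
            "NI_occ": float(mean_ni.mean()),
        })
    return pd.DataFrame(rows)


def supplementary_measures(
    cohort: list[SubjectData],
    networks: dict[tuple[str, str], FunctionalNetwork] | None,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Table-4-style occipital comparisons: relative low-alpha (6-9 Hz) and
    alpha (7.5-12.5 Hz) power from broadband re-referenced segments, and
    occipital connectivity strength from the functional networks.

    ``networks`` maps (subject_id, segment_id) to an inferred network; pass
    ``None`` to skip the connectivity rows.
    """
    power_rows = []
    for subj in cohort:
        rec = {"subject_id": subj.subject_id, "group": subj.group}
        for band, tag in (((6.0, 9.0), "low_alpha"), ((7.5, 12.5), "alpha")):
            for ch in OCCIPITAL_CHANNELS:
                vals = []
                for seg in subj.segments:
                    s = rereference_average(downsample(seg, config.target_fs))
                    vals.append(relative_band_power(s, band, ch))
                rec[f"{tag}_{ch}"] = float(np.mean(vals))
        if networks is not None:
            for ch in OCCIPITAL_CHANNELS:
                vals = [
                    node_strength(networks[(subj.subject_id, seg.segment_id)], ch)
                    for seg in subj.segments
                    if (subj.subject_id, seg.segment_id) in networks
                ]
                if vals:
                    rec[f"strength_{ch}"] = float(np.mean(vals))
        power_rows.append(rec)
    df = pd.DataFrame(power_rows)

    out = []
    for col in [c for c in df.columns if c not in ("subject_id", "group")]:
        a, b = _group_values(df, col)
        r = ranksum(a, b, tail="right")
        e = bootstrap_median_diff(a, b, n_boot=config.n_boot, seed=config.seed)
        measure, ch = col.rsplit("_", 1)
        out.append({
            "measure": measure, "node": ch, "p": r.p, "U": r.W, "z": r.z,
            "effect_size": e.median_diff, "ci_low": e.ci_low,
            "ci_high": e.ci_high,
        })
    return pd.DataFrame(out)
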