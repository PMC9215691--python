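"""Synthetic EEG-like cohorts with controllable phase-coupling ground truth.

The generator builds band-limited (default 6-9 Hz) multichannel signals as
mixtures of latent narrowband rhythm sources: one globally shared source,
one source per lobe (frontal / central / posterior), one channel-specific
source per channel, and optionally one source per explicitly coupled channel
pair.  Each source is a unit-amplitude phasor with a random carrier
frequency in the band and slow phase diffusion; a channel observes the real
part of its weighted source mixture plus white observation noise.

Because sources are mutually independent, the complex coherence of a channel
pair is exactly the overlap of their mixing weights -- pairwise coupling is
controlled directly and independently per pair, with no coherence leaking
between pairs that do not share a source.  Pair lags are imposed through the
per-channel phase factors applied to the shared sources; with the default
latent channel offsets (evenly spaced around the full circle) all pairwise
lags are well away from the zero-lag rejection threshold, and the common
average reference removes almost none of the shared rhythm.

A two-group cohort layer adds between-subject and between-segment jitter on
the mixing shares and, in the "PPR-like" group, boosts the loading of the
occipital channels O1/O2 on the globally shared rhythm.  This raises the
coherence of every O1/O2-involved pair (the occipital rows and columns of
the coupling structure) while leaving all other pairs untouched -- the
resting-state signature the analysis pipeline is designed to detect.

Nothing here attempts realistic broadband EEG: no 1/f background, no
artifacts, no photic stimulation.  The point is a ground-truthed null and
alternative for the network-inference and ictogenicity stages.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .segment import (
    CHANNELS_1020,
    CHANNEL_REGIONS,
    EEGSegment,
    OCCIPITAL_CHANNELS,
)

__all__ = [
    "CouplingSpec",
    "CohortSpec",
    "SubjectData",
    "channel_phase_offsets",
    "default_lag_matrix",
    "default_coupling_spec",
    "cohort_baseline_spec",
    "coherence_matrix",
    "generate_segment",
    "generate_cohort",
    "write_fixture",
    "read_fixture",
]

#: floor on the channel-specific source share; keeps every channel's signal
#: from being fully explained by shared sources
_MIN_OWN_SHARE = 0.05


# ----------------------------------------------------------------------
# latent offsets and lags
# ----------------------------------------------------------------------
def channel_phase_offsets(seed: int = 7, n: int = 20) -> np.ndarray:
    """Latent per-channel phase offsets, evenly spaced over the full circle.

    Shared sources reach channel i with phase factor exp(1j * alpha_i), so
    the realized lag of any coherent pair is alpha_i - alpha_j.  Even
    spacing over [0, 2*pi) keeps the minimum pairwise offset at 2*pi/n
    (0.314 rad for 20 channels, an order of magnitude above the zero-lag
    rejection threshold) and makes the offsets average to zero as phasors,
    so the common average reference barely attenuates shared rhythms.
    """
    rng = np.random.default_rng(seed)
    alpha = np.arange(n) * 2.0 * np.pi / n
    rng.shuffle(alpha)
    return alpha


def default_lag_matrix(seed: int = 7, n: int = 20) -> np.ndarray:
    """Antisymmetric pair-lag matrix alpha_i - alpha_j from the latent
    offsets (wrapped to (-pi, pi])."""
    alpha = channel_phase_offsets(seed, n)
    lag = alpha[:, None] - alpha[None, :]
    return np.angle(np.exp(1j * lag))


# ----------------------------------------------------------------------
# specs
# ----------------------------------------------------------------------
@dataclass
class CouplingSpec:
    """Ground-truth description of one synthetic segment.

    ``pair_coupling[i, j]`` in [0, 1] is the mixing share each of channels
    *i*, *j* devotes to a source private to that pair; the pair's complex
    coherence is (up to share renormalization) exactly that value, at phase
    ``pair_lag[i, j]`` (radians, antisymmetric, the mean of phi_i - phi_j).
    ``global_share`` and ``regional_share`` (scalar or per channel) assign
    weight to the globally shared and per-lobe rhythm sources, giving the
    diffuse background coherence of resting alpha; the remaining weight goes
    to a channel-specific source.  Rows whose requested shares exceed 1 are
    renormalized proportionally.
    """

    pair_coupling: np.ndarray
    pair_lag: np.ndarray
    n_channels: int = 20
    channel_labels: tuple[str, ...] = CHANNELS_1020
    global_share: float | np.ndarray = 0.0
    regional_share: float | np.ndarray = 0.0
    channel_offsets: np.ndarray | None = None
    oscillator_band: tuple[float, float] = (6.0, 9.0)
    phase_diffusion: float = 1.0  # rad^2/s of each source's phase walk
    observation_noise_sd: float = 0.3
    fs: float = 250.0
    duration: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.pair_coupling = np.asarray(self.pair_coupling, dtype=float)
        self.pair_lag = np.asarray(self.pair_lag, dtype=float)
        self.global_share = np.broadcast_to(
            np.asarray(self.global_share, dtype=float), (self.n_channels,)
        ).copy()
        self.regional_share = np.broadcast_to(
            np.asarray(self.regional_share, dtype=float), (self.n_channels,)
        ).copy()
        if self.channel_offsets is None:
            self.channel_offsets = channel_phase_offsets(n=self.n_channels)
        self.channel_offsets = np.asarray(self.channel_offsets, dtype=float)

    def validate(self) -> None:
        k, lag = self.pair_coupling, self.pair_lag
        n = self.n_channels
        if len(self.channel_labels) != n:
            raise ValueError("channel_labels length must equal n_channels")
        if k.shape != (n, n) or lag.shape != (n, n):
            raise ValueError(
                "pair_coupling and pair_lag must be n_channels x n_channels"
            )
        if not np.allclose(k, k.T):
            raise ValueError("pair_coupling must be symmetric")
        if np.any(np.diag(k) != 0):
            raise ValueError("pair_coupling diagonal must be zero")
        if np.any(k < 0) or np.any(k > 1):
            raise ValueError("pair_coupling entries must lie in [0, 1]")
        if not np.allclose(np.angle(np.exp(1j * (lag + lag.T))), 0, atol=1e-8):
            raise ValueError("pair_lag must be antisymmetric (modulo 2*pi)")
        if np.any(self.global_share < 0) or np.any(self.regional_share < 0):
            raise ValueError("source shares must be non-negative")
        lo, hi = self.oscillator_band
        if not lo < hi:
            raise ValueError("oscillator_band lower edge must be below upper edge")
        if not self.fs > 2.0 * hi:
            raise ValueError("fs must exceed twice the oscillator_band upper edge")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.observation_noise_sd < 0 or self.phase_diffusion < 0:
            raise ValueError("noise parameters must be non-negative")

    def mixing_shares(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-channel source shares after renormalization.

        Returns ``(global, regional, pair, own)`` with ``pair`` the full
        n x n matrix of per-pair shares; every channel's shares sum to 1.
        """
        n = self.n_channels
        g = self.global_share.copy()
        r = self.regional_share.copy()
        p = self.pair_coupling.copy()
        requested = g + r + p.sum(axis=1)
        scale = np.minimum(1.0, (1.0 - _MIN_OWN_SHARE) / np.maximum(requested, 1e-12))
        g *= scale
        r *= scale
        # per-channel share of each pair source (rows scaled by that
        # channel's factor; the pair's coherence is the geometric mean)
        p = p * scale[:, None]
        own = 1.0 - (g + r + p.sum(axis=1))
        return g, r, p, own


@dataclass
class CohortSpec:
    """Two-group cohort layout mirroring a PPR vs non-PPR study design.

    ``occipital_boost`` moves that much mixing share of the O1/O2 channels
    onto the globally shared rhythm (taken from their channel-specific and
    regional shares), which raises the coherence of every pair involving an
    occipital channel in group A while leaving other pairs unchanged.
    """

    baseline: CouplingSpec
    n_group_a: int = 26  # "PPR"-like group, receives the occipital boost
    n_group_b: int = 20
    segments_per_subject: int = 3
    occipital_boost: float = 0.2
    subject_sd: float = 0.04
    segment_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        self.baseline.validate()
        if self.segments_per_subject < 1:
            raise ValueError("segments_per_subject must be >= 1")
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ValueError("both groups need at least one subject")
        if self.subject_sd < 0 or self.segment_sd < 0:
            raise ValueError("jitter scales must be non-negative")
        if not 0 <= self.occipital_boost <= 1:
            raise ValueError("occipital_boost must lie in [0, 1]")


@dataclass
class SubjectData:
    """One synthetic subject: segments plus coherence ground truth."""

    subject_id: str
    group: str  # "PPR" or "nonPPR"
    segments: list[EEGSegment]
    true_couplings: list[np.ndarray] | None = None


# ----------------------------------------------------------------------
# canonical specs
# ----------------------------------------------------------------------
def default_coupling_spec(seed: int = 0, **overrides) -> CouplingSpec:
    """Segment spec with no coupling at all (independent channels)."""
    n = overrides.pop("n_channels", 20)
    spec = CouplingSpec(
        pair_coupling=np.zeros((n, n)),
        pair_lag=np.zeros((n, n)),
        n_channels=n,
        seed=seed,
        **overrides,
    )
    spec.validate()
    return spec


def cohort_baseline_spec(
    seed: int = 0,
    global_share: float = 0.30,
    regional_share: float = 0.50,
    **overrides,
) -> CouplingSpec:
    """Baseline resting-EEG-like spec: diffuse global + per-lobe coherence.

    Within-lobe coherence is ``global + regional`` (0.80 -> PLV around
    0.7, comfortably significant), across lobes ``global`` alone (0.30,
    hovering at the significance threshold), giving functional networks
    enough total weight that the simulated seizure propensity sweeps its
    full range over the standard coupling interval for essentially every
    segment.
    """
    n = overrides.pop("n_channels", 20)
    spec = CouplingSpec(
        pair_coupling=np.zeros((n, n)),
        pair_lag=default_lag_matrix(n=n),
        n_channels=n,
        global_share=global_share,
        regional_share=regional_share,
        seed=seed,
        **overrides,
    )
    spec.validate()
    return spec


def _apply_occipital_boost(spec: CouplingSpec, boost: float) -> CouplingSpec:
    """Shift occipital mixing share onto the global rhythm source."""
    if boost == 0.0:
        return spec
    g = spec.global_share.copy()
    r = spec.regional_share.copy()
    for ch in OCCIPITAL_CHANNELS:
        if ch not in spec.channel_labels:
            continue
        i = spec.channel_labels.index(ch)
        g[i] = min(g[i] + boost, 1.0 - _MIN_OWN_SHARE)
        r[i] = max(r[i] - boost / 2.0, 0.0)
    return replace(spec, global_share=g, regional_share=r)


def coherence_matrix(spec: CouplingSpec) -> np.ndarray:
    """Ground-truth magnitude coherence implied by the mixing shares.

    coh(i, j) = sqrt(g_i * g_j) + sqrt(r_i * r_j) * [same lobe] +
    sqrt(p_ij_i_share * p_ij_j_share); the PLV recovered downstream is a
    monotone, slightly compressive function of this value.
    """
    g, r, p, _ = spec.mixing_shares()
    labels = spec.channel_labels
    same_region = np.array(
        [
            [CHANNEL_REGIONS.get(a) == CHANNEL_REGIONS.get(b) for b in labels]
            for a in labels
        ]
    )
    coh = np.sqrt(np.outer(g, g)) + np.sqrt(np.outer(r, r)) * same_region + np.sqrt(p * p.T)
    np.fill_diagonal(coh, 0.0)
    return coh


# ----------------------------------------------------------------------
# segment generation
# ----------------------------------------------------------------------
def _narrowband_phasor(
    rng: np.random.Generator,
    n_samples: int,
    fs: float,
    band: tuple[float, float],
    diffusion: float,
) -> np.ndarray:
    """Unit-amplitude analytic rhythm: random in-band carrier + phase walk."""
    f = rng.uniform(*band)
    t = np.arange(n_samples) / fs
    walk = rng.normal(0.0, np.sqrt(diffusion / fs), n_samples).cumsum()
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    return np.exp(1j * (2.0 * np.pi * f * t + walk + phi0))


def generate_segment(spec: CouplingSpec) -> EEGSegment:
    """Simulate one multichannel segment from the latent source mixture.

    Deterministic given ``spec.seed``.  The observed signal per channel is
    the real part of its complex source mixture plus white observation
    noise; all rhythm sources live inside ``oscillator_band``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_channels
    n_samples = int(round(spec.fs * spec.duration))
    g, r, p, own = spec.mixing_shares()
    alpha = spec.channel_offsets

    def phasor() -> np.ndarray:
        return _narrowband_phasor(
            rng, n_samples, spec.fs, spec.oscillator_band, spec.phase_diffusion
        )

    analytic = np.zeros((n, n_samples), dtype=complex)

    z_global = phasor()
    for i in range(n):
        if g[i] > 0:
            analytic[i] += np.sqrt(g[i]) * np.exp(1j * alpha[i]) * z_global

    regions = [CHANNEL_REGIONS.get(c) for c in spec.channel_labels]
    for region in sorted({x for x in regions if x is not None}):
        z_region = phasor()
        for i in range(n):
            if regions[i] == region and r[i] > 0:
                analytic[i] += np.sqrt(r[i]) * np.exp(1j * alpha[i]) * z_region

    for i in range(n):
        for j in range(i + 1, n):
            if p[i, j] > 0:
                z_pair = phasor()
                half = spec.pair_lag[i, j] / 2.0
                analytic[i] += np.sqrt(p[i, j]) * np.exp(1j * half) * z_pair
                analytic[j] += np.sqrt(p[j, i]) * np.exp(-1j * half) * z_pair

    for i in range(n):
        analytic[i] += np.sqrt(own[i]) * phasor()

    data = analytic.real
    if spec.observation_noise_sd > 0:
        data = data + spec.observation_noise_sd * rng.standard_normal(data.shape)
    return EEGSegment(data=data, fs=spec.fs, channel_labels=spec.channel_labels)


# ----------------------------------------------------------------------
# cohorts
# ----------------------------------------------------------------------
def _jitter_vec(v: np.ndarray, sd: float, rng: np.random.Generator,
                hi: float = 1.0) -> np.ndarray:
    if sd == 0:
        return v.copy()
    return np.clip(v + rng.normal(0.0, sd, size=v.shape), 0.0, hi)


def _jitter_pairs(k: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric truncated-normal jitter on pair couplings (lags untouched)."""
    if sd == 0:
        return k.copy()
    n = k.shape[0]
    eps = np.triu(rng.normal(0.0, sd, size=(n, n)), k=1)
    eps = eps + eps.T
    out = np.clip(k + eps * (k > 0), 0.0, 1.0)
    np.fill_diagonal(out, 0.0)
    return out


def generate_cohort(spec: CohortSpec) -> list[SubjectData]:
    """Generate the full two-group cohort with ground truth attached.

    Group A ("PPR") receives the occipital boost on the baseline spec; both
    groups then get subject-level and segment-level truncated-normal jitter
    on the mixing shares (and on any nonzero pair couplings).  Everything is
    reproducible from ``spec.seed``; ``true_couplings`` holds the realized
    per-segment coherence ground truth from :func:`coherence_matrix`.
    """
    spec.validate()
    subjects: list[SubjectData] = []
    counter = 0
    for group, n_subj, tag in (
        ("PPR", spec.n_group_a, "A"),
        ("nonPPR", spec.n_group_b, "B"),
    ):
        group_spec = spec.baseline
        if group == "PPR":
            group_spec = _apply_occipital_boost(spec.baseline, spec.occipital_boost)
        for s in range(n_subj):
            subject_id = f"{tag}{s + 1:02d}"
            subj_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=spec.seed, spawn_key=(counter,))
            )
            subj_spec = replace(
                group_spec,
                global_share=_jitter_vec(
                    group_spec.global_share, spec.subject_sd, subj_rng
                ),
                regional_share=_jitter_vec(
                    group_spec.regional_share, spec.subject_sd, subj_rng
                ),
                pair_coupling=_jitter_pairs(
                    group_spec.pair_coupling, spec.subject_sd, subj_rng
                ),
            )
            segments, truths = [], []
            for gi in range(spec.segments_per_subject):
                seg_seed = int(
                    np.random.SeedSequence(
                        entropy=spec.seed, spawn_key=(counter, gi)
                    ).generate_state(1)[0] % (2**31)
                )
                seg_spec = replace(
                    subj_spec,
                    global_share=_jitter_vec(
                        subj_spec.global_share, spec.segment_sd, subj_rng
                    ),
                    regional_share=_jitter_vec(
                        subj_spec.regional_share, spec.segment_sd, subj_rng
                    ),
                    pair_coupling=_jitter_pairs(
                        subj_spec.pair_coupling, spec.segment_sd, subj_rng
                    ),
                    seed=seg_seed,
                )
                seg = generate_segment(seg_spec)
                seg.subject_id = subject_id
                seg.segment_id = f"seg{gi + 1}"
                segments.append(seg)
                truths.append(coherence_matrix(seg_spec))
            subjects.append(SubjectData(subject_id, group, segments, truths))
            counter += 1
    return subjects


# ----------------------------------------------------------------------
# fixtures on disk (headered CSV per segment + manifest)
# ----------------------------------------------------------------------
def write_fixture(cohort: list[SubjectData], directory) -> str:
    """Write the cohort as one CSV per segment plus a manifest CSV.

    Returns the manifest path.  Manifest columns: subject_id, group,
    segment_file.
    """
    os.makedirs(directory, exist_ok=True)
    rows = []
    for subj in cohort:
        for seg in subj.segments:
            fname = f"{subj.subject_id}_{seg.segment_id}.csv"
            seg.to_csv(os.path.join(directory, fname))
            rows.append(
                {"subject_id": subj.subject_id, "group": subj.group,
                 "segment_file": fname}
            )
    manifest = os.path.join(directory, "manifest.csv")
    pd.DataFrame(rows, columns=["subject_id", "group", "segment_file"]).to_csv(
        manifest, index=False
    )
    return manifest


def read_fixture(directory) -> list[SubjectData]:
    """Read a cohort previously written by :func:`write_fixture`.

    Raises ``FileNotFoundError`` naming any segment file referenced by the
    manifest that is absent, and ``ValueError`` on a malformed manifest.
    """
    manifest = os.path.join(directory, "manifest.csv")
    if not os.path.exists(manifest):
        raise FileNotFoundError(f"manifest not found: {manifest}")
    df = pd.read_csv(manifest)
    required = {"subject_id", "group", "segment_file"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest {manifest} lacks columns {sorted(required)}")
    subjects: dict[str, SubjectData] = {}
    for row in df.itertuples(index=False):
        path = os.path.join(directory, row.segment_file)
        if not os.path.exists(path):
            raise FileNotFoundError(
                f"manifest references missing segment file: {row.segment_file}"
            )
        seg = EEGSegment.from_csv(path)
        subj = subjects.setdefault(
            row.subject_id, SubjectData(row.subject_id, row.group, [])
        )
        subj.segments.append(seg)
    return list(subjects.values())
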