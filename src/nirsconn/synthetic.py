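"""Ground-truth generators: MVAR networks, latent ROI haemodynamics, raw
two-wavelength recordings, and clinical/reading cohorts with planted mediation.

Everything downstream of this module (preprocessing, connectivity estimation,
significance testing, mediation) can be tested against the known quantities
planted here.  Latent dynamics are band-limited by construction: autoregressive
self-poles are placed so spectral power concentrates below ~0.08 Hz at the
default sampling rate, matching the neurovascular-coupling band the analysis
averages over.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import (
    ROI_LABELS,
    RawIntensityRecording,
    default_roi_map,
    dpf,
    extinction_matrix,
)

__all__ = [
    "StabilityError",
    "GroundTruthNetwork",
    "ArtifactSpec",
    "MediationEffect",
    "CohortSpec",
    "generate_network",
    "simulate_roi_timeseries",
    "synthesize_raw_recording",
    "generate_cohort",
    "default_mediation_effects",
    "DEFAULT_SEED",
    "DEFAULT_FS",
]

DEFAULT_SEED = 0
#: Default sampling rate (Hz); typical for continuous-wave fNIRS systems.
DEFAULT_FS = 7.8125


class StabilityError(RuntimeError):
    """Raised when a stable MVAR could not be constructed."""


def companion_matrix(coeffs: np.ndarray) -> np.ndarray:
    """Companion form of an MVAR(P): coeffs has shape (P, M, M)."""
    p, m, _ = coeffs.shape
    top = np.concatenate([coeffs[r] for r in range(p)], axis=1)
    if p == 1:
        return top
    eye = np.eye(m * (p - 1))
    bottom = np.concatenate([eye, np.zeros((m * (p - 1), m))], axis=1)
    return np.vstack([top, bottom])


def spectral_radius(coeffs: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(coeffs)))))


@dataclass
class GroundTruthNetwork:
    """A time-(in)varying MVAR ground truth over ``n_rois`` regions.

    ``edges`` are ordered (source, target) pairs; ``coupling`` the per-edge
    lag-1 coefficient; ``tv_profile`` optionally modulates each edge over the
    simulation ('constant', 'ramp' from 0 to full, or 'step' switching on at
    mid-series).  Self-dynamics sit on the diagonal at lag 1.
    """

    n_rois: int = 7
    edges: list = field(default_factory=list)
    coupling: dict = field(default_factory=dict)  # (src, tgt) -> coefficient
    model_order: int = 3
    self_coupling: float = 0.94
    tv_profile: dict = field(default_factory=dict)  # (src, tgt) -> profile name

    def __post_init__(self) -> None:
        seen = set()
        for src, tgt in self.edges:
            if src == tgt:
                raise ValueError("self-edges are not allowed")
            if (src, tgt) in seen:
                raise ValueError(f"duplicate edge {(src, tgt)}")
            seen.add((src, tgt))
        for c in self.coupling.values():
            if abs(c) >= 1:
                raise ValueError("edge coupling magnitudes must be < 1")

    def coeff_tensor(self, frac: float = 1.0) -> np.ndarray:
        """(P, M, M) coefficient tensor at relative time ``frac`` in [0, 1].

        With ``model_order >= 2`` the self-dynamics are a double real pole at
        ``self_coupling`` (lag-1 coefficient 2*rho, lag-2 coefficient -rho^2),
        which concentrates >80% of the spectral power below 0.08 Hz at the
        default sampling rate; at order 1 a single pole is used.

        Edges are plain lag-1 coefficients.  Feedback loops between such
        strongly resonant nodes diverge unless couplings are negligible, so
        the default generator samples acyclic edge patterns (see
        :func:`generate_network`), for which the system is block-triangular
        and stable at any per-edge |c| < 1.
        """
        a = np.zeros((self.model_order, self.n_rois, self.n_rois))
        rho = self.self_coupling
        if self.model_order >= 2:
            a[0][np.diag_indices(self.n_rois)] = 2.0 * rho
            a[1][np.diag_indices(self.n_rois)] = -(rho**2)
        else:
            a[0][np.diag_indices(self.n_rois)] = rho
        for src, tgt in self.edges:
            mod = 1.0
            profile = self.tv_profile.get((src, tgt), "constant")
            if profile == "ramp":
                mod = frac
            elif profile == "step":
                mod = 1.0 if frac >= 0.5 else 0.0
            elif profile != "constant":
                raise ValueError(f"unknown tv_profile {profile!r}")
            a[0, tgt, src] = self.coupling[(src, tgt)] * mod
        return a

    def is_stable(self) -> bool:
        return spectral_radius(self.coeff_tensor(1.0)) < 1.0

    def to_dict(self) -> dict:
        return {
            "n_rois": self.n_rois,
            "edges": [list(e) for e in self.edges],
            "coupling": {f"{s}->{t}": c for (s, t), c in self.coupling.items()},
            "model_order": self.model_order,
            "self_coupling": self.self_coupling,
            "tv_profile": {f"{s}->{t}": p for (s, t), p in self.tv_profile.items()},
        }


def generate_network(
    n_rois: int = 7,
    edge_density: float = 0.2,
    coupling_range: tuple = (0.15, 0.35),
    model_order: int = 3,
    seed: int = DEFAULT_SEED,
    self_coupling: float = 0.94,
    tv_profile: str = "constant",
    max_retries: int = 60,
    acyclic: bool = True,
) -> GroundTruthNetwork:
    """Random directed network with a verifiably stable MVAR realization.

    ``edge_density`` in [0, 1] fixes the edge count exactly
    (round(density * n_rois * (n_rois - 1))); couplings are drawn uniformly
    from ``coupling_range``.  With ``acyclic`` (default) edges are drawn
    respecting a random node ordering for as long as possible, so typical
    sparse networks are feedback-free and stable at full coupling strength;
    any cycle-closing edges (needed above ~50% density, or with
    ``acyclic=False``) can force the stability retry loop, which shrinks all
    couplings by 30% per attempt until the companion spectral radius drops
    below 1, up to ``max_retries``; heavily cyclic patterns therefore come
    back stable but weakly coupled.
    """
    if not 0.0 <= edge_density <= 1.0:
        raise ValueError("edge_density must be in [0, 1]")
    lo, hi = coupling_range
    if not (-1.0 < lo <= hi < 1.0):
        raise ValueError("coupling_range must lie within (-1, 1)")
    rng = np.random.default_rng(seed)
    pairs = [(s, t) for s in range(n_rois) for t in range(n_rois) if s != t]
    n_edges = int(round(edge_density * len(pairs)))
    if acyclic and n_edges:
        order = rng.permutation(n_rois)
        rank = {int(node): i for i, node in enumerate(order)}
        forward = [p for p in pairs if rank[p[0]] < rank[p[1]]]
        backward = [p for p in pairs if rank[p[0]] > rank[p[1]]]
        pool = [forward[i] for i in rng.permutation(len(forward))] + [
            backward[i] for i in rng.permutation(len(backward))
        ]
        edges = pool[:n_edges]
    else:
        idx = rng.choice(len(pairs), size=n_edges, replace=False) if n_edges else []
        edges = [pairs[i] for i in idx]
    coupling = {e: float(rng.uniform(lo, hi)) for e in edges}

    shrink = 1.0
    for _ in range(max_retries + 1):
        net = GroundTruthNetwork(
            n_rois=n_rois,
            edges=edges,
            coupling={e: c * shrink for e, c in coupling.items()},
            model_order=model_order,
            self_coupling=self_coupling,
            tv_profile={e: tv_profile for e in edges} if tv_profile != "constant" else {},
        )
        if net.is_stable():
            return net
        shrink *= 0.7
    raise StabilityError(
        f"could not stabilize network after {max_retries} coupling reductions"
    )


def simulate_roi_timeseries(
    network: GroundTruthNetwork,
    n_samples: int = 3000,
    fs: float = DEFAULT_FS,
    noise_sd: float = 1.0,
    seed: int = DEFAULT_SEED,
    burn_in: int = 200,
) -> tuple[np.ndarray, dict]:
    """Simulate the MVAR recursion; returns (series (n_rois, n_samples), truth).

    Time-varying profiles are evaluated over the retained samples (the burn-in
    runs at the t=0 coefficients).  The returned series is mean-centered per
    channel.  Raises :class:`StabilityError` for unstable networks.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if n_samples <= 10 * network.model_order:
        raise ValueError("n_samples must exceed 10 x model_order")
    if not network.is_stable():
        raise StabilityError("network MVAR is unstable")
    rng = np.random.default_rng(seed)
    m, p = network.n_rois, network.model_order
    total = n_samples + burn_in
    x = np.zeros((m, total))
    noise = rng.normal(0.0, noise_sd, size=(m, total))
    time_varying = bool(network.tv_profile)
    a0 = network.coeff_tensor(0.0)
    for t in range(p, total):
        if time_varying and t >= burn_in:
            frac = (t - burn_in) / max(n_samples - 1, 1)
            a = network.coeff_tensor(frac)
        else:
            a = a0
        acc = noise[:, t].copy()
        for r in range(p):
            acc += a[r] @ x[:, t - 1 - r]
        x[:, t] = acc
    out = x[:, burn_in:]
    out = out - out.mean(axis=1, keepdims=True)
    truth = {
        "edges": list(network.edges),
        "coupling": dict(network.coupling),
        "tv_profile": dict(network.tv_profile),
        "fs": fs,
        "noise_sd": noise_sd,
    }
    return out, truth


@dataclass
class ArtifactSpec:
    """Confound levels injected into synthetic recordings.

    Rates are events per minute; amplitudes are multiples of the clean
    channel SD (Mayer/systemic are relative amplitudes of shared components).
    """

    spike_rate: float = 0.5
    spike_amplitude: float = 8.0
    shift_rate: float = 0.2
    shift_amplitude: float = 4.0
    mayer_amplitude: float = 0.5
    mayer_freq_hz: float = 0.1
    global_systemic_amplitude: float = 0.5
    channel_noise_sd: float = 0.2

    def __post_init__(self) -> None:
        for name in (
            "spike_rate",
            "spike_amplitude",
            "shift_rate",
            "shift_amplitude",
            "mayer_amplitude",
            "global_systemic_amplitude",
            "channel_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def none(cls) -> "ArtifactSpec":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.1, 0.0, 0.0)


def _slow_noise(n: int, fs: float, cutoff_hz: float, rng) -> np.ndarray:
    """Unit-variance low-pass (AR(1)) noise with pole near ``cutoff_hz``."""
    rho = float(np.exp(-2.0 * np.pi * cutoff_hz / fs))
    e = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = e[0]
    for t in range(1, n):
        x[t] = rho * x[t - 1] + e[t]
    sd = x.std()
    return x / sd if sd > 0 else x


def synthesize_raw_recording(
    roi_series: np.ndarray,
    roi_map: pd.DataFrame | None = None,
    fs: float = DEFAULT_FS,
    age: float = 10.0,
    artifact_spec: ArtifactSpec | None = None,
    seed: int = DEFAULT_SEED,
    baseline_intensity: float = 1.0,
    distance_cm: float = 3.0,
    hbr_ratio: float = -0.33,
    amplitude_um: float = 0.3,
    n_background_channels: int = 42,
) -> RawIntensityRecording:
    """Forward model: latent ROI series -> channel HbO/HbR -> two-wavelength light.

    Each mapped channel receives its ROI's latent series (scaled to
    ``amplitude_um`` micromolar per unit latent SD) plus channel noise, a
    shared slow systemic component, a shared ~0.1 Hz Mayer oscillation, and
    Poisson spike/shift artifacts.  HbR mirrors HbO at ``hbr_ratio``.  The
    modified Beer-Lambert law with DPF(age) then produces strictly positive
    intensities at 760 and 850 nm.

    ``n_background_channels`` unmapped channels carry independent slow
    haemodynamics plus the same shared confounds, emulating the bulk of a
    whole-head montage outside the reading network (the default montage totals
    122 channels: 2 x 40 mapped + 42 background).  They are dropped at ROI
    pooling but matter before that: the spatial-regression stage estimates the
    systemic component from *all* channels, and on a whole-head montage that
    estimate is dominated by systemic physiology rather than any one region's
    activity.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    if baseline_intensity <= 0:
        raise ValueError("baseline intensity must be positive")
    spec = ArtifactSpec() if artifact_spec is None else artifact_spec
    roi_map = default_roi_map(("left",)) if roi_map is None else roi_map
    rng = np.random.default_rng(seed)
    roi_series = np.asarray(roi_series, dtype=float)
    n_rois, n_t = roi_series.shape
    roi_index = {label: i for i, label in enumerate(ROI_LABELS[:n_rois])}
    missing = set(roi_map["roi"]) - set(roi_index)
    if missing:
        raise ValueError(f"roi_map references ROIs without latent series: {missing}")

    latent_sd = roi_series.std(axis=1, keepdims=True)
    latent_sd[latent_sd == 0] = 1.0
    latent_um = amplitude_um * roi_series / latent_sd

    minutes = n_t / fs / 60.0
    t = np.arange(n_t) / fs
    mayer = np.sin(2 * np.pi * spec.mayer_freq_hz * t + rng.uniform(0, 2 * np.pi))
    systemic = (
        _slow_noise(n_t, fs, 0.04, rng)
        if spec.global_systemic_amplitude > 0
        else np.zeros(n_t)
    )

    pathlen = distance_cm * dpf(age)
    E = extinction_matrix((760.0, 850.0))

    channel_latents = [latent_um[roi_index[row.roi]] for row in roi_map.itertuples()]
    channel_ids = [(int(row.source), int(row.detector)) for row in roi_map.itertuples()]
    rho_bg = float(np.exp(-2.0 * np.pi * 0.03 / fs))  # slow background dynamics
    for k in range(n_background_channels):
        e = rng.standard_normal(n_t)
        bg = np.empty(n_t)
        bg[0] = e[0]
        for t_i in range(1, n_t):
            bg[t_i] = rho_bg * bg[t_i - 1] + e[t_i]
        bg = amplitude_um * (bg - bg.mean()) / (bg.std() or 1.0)
        channel_latents.append(bg)
        channel_ids.append((900 + k, 900 + k))

    intens, wls, srcs, dets = [], [], [], []
    for (src_id, det_id), base in zip(channel_ids, channel_latents):
        base = base.copy()
        sd = amplitude_um
        hbo = base + spec.channel_noise_sd * sd * rng.standard_normal(n_t)
        hbo += spec.global_systemic_amplitude * sd * systemic
        hbo += spec.mayer_amplitude * sd * mayer
        for _ in range(rng.poisson(spec.spike_rate * minutes)):
            k = rng.integers(0, n_t)
            width = max(1, int(round(0.25 * fs)))
            tail = np.arange(min(width * 4, n_t - k))
            hbo[k : k + tail.size] += (
                spec.spike_amplitude * sd * rng.choice([-1.0, 1.0]) * np.exp(-tail / width)
            )
        for _ in range(rng.poisson(spec.shift_rate * minutes)):
            k = rng.integers(1, n_t)
            hbo[k:] += spec.shift_amplitude * sd * rng.choice([-1.0, 1.0])
        hbr = hbr_ratio * hbo + 0.1 * sd * rng.standard_normal(n_t) * (
            spec.channel_noise_sd > 0
        )
        od = (E @ np.vstack([hbo, hbr])) * pathlen  # (2, n_t)
        for w, wl in enumerate((760.0, 850.0)):
            intens.append(baseline_intensity * np.exp(-od[w]))
            wls.append(wl)
            srcs.append(src_id)
            dets.append(det_id)

    return RawIntensityRecording(
        intensities=np.vstack(intens),
        wavelength=np.asarray(wls),
        source=np.asarray(srcs),
        detector=np.asarray(dets),
        fs=fs,
        subject_age=age,
        source_detector_distance_cm=distance_cm,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

SUBTESTS = ("WRDC", "VOC", "MORPH", "SEN", "EFFIC", "RCOMP")

CLINICAL_VARIABLES = (
    "age_first_ci",
    "age_first_ha",
    "dur_deaf_first_ci",
    "dur_deaf_left_ci",
    "dur_deaf_right_ci",
    "time_between_bilateral",
    "age_bilateral_ci",
    "age_at_testing",
    "head_size",
    "hearing_age",
)

#: Predictor factor names mirroring the three-component clinical structure.
FACTORS = ("primary", "secondary", "development")


@dataclass(frozen=True)
class MediationEffect:
    """A planted (predictor factor, connection, subtest) mediation triple.

    ``a`` is the predictor->connectivity path, ``b`` the connectivity->reading
    path, ``direct`` the predictor->reading path not through connectivity; the
    true indirect effect is a*b (standardized units).
    """

    predictor: str
    connection: tuple  # (source_roi_label, target_roi_label)
    subtest: str
    a: float
    b: float
    direct: float = 0.0


def default_mediation_effects() -> list[MediationEffect]:
    """Timing-of-intervention effects mediated by SMG->IPL on every subtest."""
    return [
        MediationEffect("primary", ("SMG", "IPL"), s, a=-0.5, b=0.4, direct=-0.15)
        for s in SUBTESTS
    ]


@dataclass
class CohortSpec:
    """Cohort layout and score scaling for the synthetic study population."""

    n_ci: int = 50
    n_th: int = 25
    mediation_effects: list = field(default_factory=default_mediation_effects)
    score_mean: float = 250.0
    score_sd: float = 15.0
    score_min: float = 190.0
    score_max: float = 310.0
    #: group-level shift of standardized scores (SD units * score_sd); the
    #: defaults give TH readers ~0.8 SD advantage while the 2:1 CI:TH mix
    #: keeps the combined subtest mean at ``score_mean``.
    ci_offset_sd: float = -4.0 / 15.0
    th_offset_sd: float = 8.0 / 15.0
    development_coef: float = 0.3
    general_reading_coef: float = 0.5
    th_age_coef: float = 0.55
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not self.score_min < self.score_mean < self.score_max:
            raise ValueError("score bounds must bracket the mean")
        if self.n_ci <= 0 or self.n_th <= 0:
            raise ValueError("group sizes must be positive")


def _all_connections() -> list[tuple]:
    return [(s, t) for s in ROI_LABELS for t in ROI_LABELS if s != t]


def generate_cohort(spec: CohortSpec | None = None) -> dict:
    """Generate clinical, reading and connectivity tables with planted mediation.

    Returns a dict with keys ``clinical``, ``reading``, ``connectivity``
    (pandas DataFrames indexed by subject id) and ``truth`` (latent factors
    and the planted effects).  Clinical variables are drawn in three
    correlated blocks (primary intervention / secondary intervention /
    development) so a PCA of the CI group recovers three components; planted
    effects route factor -> connection strength -> reading score, and scores
    are mapped to the 250/15 scale and clamped to [score_min, score_max].
    """
    spec = CohortSpec() if spec is None else spec
    rng = np.random.default_rng(spec.seed)
    n_ci, n_th = spec.n_ci, spec.n_th
    n = n_ci + n_th
    subjects = [f"CI{i:04d}" for i in range(n_ci)] + [f"TH{i:04d}" for i in range(n_th)]
    group = np.array(["CI"] * n_ci + ["TH"] * n_th)

    z1 = rng.standard_normal(n_ci)  # primary intervention factor
    z2 = rng.standard_normal(n_ci)  # secondary intervention factor
    z3 = rng.standard_normal(n)  # development factor (both groups)
    g = rng.standard_normal(n)  # general reading ability

    def mix(z, load, size):
        return load * z + np.sqrt(1 - load**2) * rng.standard_normal(size)

    # --- clinical block 1: primary intervention (CI only) ---
    age_first_ci = np.clip(1.98 + 0.98 * mix(z1, 0.85, n_ci), 0.3, None)
    age_first_ha = np.clip(1.0 + 0.85 * mix(z1, 0.80, n_ci), 0.05, None)
    dur_deaf_first_ci = np.clip(age_first_ci + 0.2 * rng.standard_normal(n_ci), 0.0, None)
    dur_deaf_left_ci = np.clip(age_first_ci + 0.25 * rng.standard_normal(n_ci), 0.0, None)
    # --- block 2: secondary intervention ---
    time_between = np.clip(1.43 + 2.2 * mix(z2, 0.85, n_ci), 0.0, None)
    # reporting jitter keeps the clinical table full rank, as in real records
    age_bilateral = age_first_ci + time_between + 0.15 * rng.standard_normal(n_ci)
    dur_deaf_right_ci = np.clip(age_bilateral + 0.3 * rng.standard_normal(n_ci), 0.0, None)
    # --- block 3: development (both groups) ---
    age_at_testing = np.clip(12.2 + 2.9 * mix(z3, 0.85, n), 7.0, 17.5)
    head_size = 49.0 + 0.25 * (age_at_testing - 12.2) + 1.0 * rng.standard_normal(n)

    hearing_age = np.empty(n)
    first_intervention = np.minimum(age_first_ci, age_first_ha)
    hearing_age[:n_ci] = age_at_testing[:n_ci] - first_intervention
    hearing_age[n_ci:] = age_at_testing[n_ci:]

    clinical = pd.DataFrame(index=pd.Index(subjects, name="subject"))
    clinical["group"] = group
    clinical["sex"] = rng.choice(["F", "M"], size=n)
    for name, vals in [
        ("age_first_ci", age_first_ci),
        ("age_first_ha", age_first_ha),
        ("dur_deaf_first_ci", dur_deaf_first_ci),
        ("dur_deaf_left_ci", dur_deaf_left_ci),
        ("dur_deaf_right_ci", dur_deaf_right_ci),
        ("time_between_bilateral", time_between),
        ("age_bilateral_ci", age_bilateral),
    ]:
        col = np.full(n, np.nan)
        col[:n_ci] = vals
        clinical[name] = col
    clinical["age_at_testing"] = age_at_testing
    clinical["head_size"] = head_size
    clinical["hearing_age"] = hearing_age

    factor_ci = {"primary": z1, "secondary": z2, "development": z3[:n_ci]}

    # --- connection strengths ---
    connections = _all_connections()
    conn_std = np.empty((n, len(connections)))
    effects_by_conn: dict[tuple, list[MediationEffect]] = {}
    for eff in spec.mediation_effects:
        if eff.predictor not in FACTORS:
            raise ValueError(f"unknown predictor factor {eff.predictor!r}")
        if eff.subtest not in SUBTESTS:
            raise ValueError(f"unknown subtest {eff.subtest!r}")
        effects_by_conn.setdefault(eff.connection, []).append(eff)

    mediator_noise = rng.standard_normal((n, len(connections)))
    a_by_conn: dict[tuple, dict[str, float]] = {}
    for c_idx, conn in enumerate(connections):
        a_paths: dict[str, float] = {}
        for eff in effects_by_conn.get(conn, []):
            prev = a_paths.get(eff.predictor)
            if prev is not None and prev != eff.a:
                raise ValueError(
                    f"conflicting a-paths for {conn} from {eff.predictor}"
                )
            a_paths[eff.predictor] = eff.a
        a_by_conn[conn] = a_paths
        explained = sum(a**2 for a in a_paths.values())
        if explained >= 1.0:
            raise ValueError(f"infeasible a-paths for connection {conn}")
        m = np.sqrt(1.0 - explained) * mediator_noise[:, c_idx]
        for factor, a in a_paths.items():
            m[:n_ci] += a * factor_ci[factor]
        conn_std[:, c_idx] = m
    # map to a PDC-like scale; TH sits ~0.75 SD above CI, as seen in practice
    conn_offset = np.where(group == "CI", -0.25, 0.5)
    conn_values = np.clip(0.35 + 0.08 * (conn_std + conn_offset[:, None]), 0.0, 1.0)
    connectivity = pd.DataFrame(
        conn_values,
        index=clinical.index,
        columns=[f"{s}->{t}" for s, t in connections],
    )

    # --- reading scores ---
    conn_lookup = {c: i for i, c in enumerate(connections)}
    reading = pd.DataFrame(index=clinical.index)
    reading["group"] = group
    for subtest in SUBTESTS:
        y = np.zeros(n)
        explained_ci = 0.0
        # factor-mediated and direct paths (CI only)
        factor_coefs: dict[str, float] = {"development": spec.development_coef}
        noise_coefs: dict[tuple, float] = {}
        for eff in spec.mediation_effects:
            if eff.subtest != subtest:
                continue
            factor_coefs[eff.predictor] = (
                factor_coefs.get(eff.predictor, 0.0) + eff.a * eff.b + eff.direct
            )
            noise_coefs[eff.connection] = noise_coefs.get(eff.connection, 0.0) + (
                eff.b * np.sqrt(1.0 - sum(a**2 for a in a_by_conn[eff.connection].values()))
            )
        for factor, coef in factor_coefs.items():
            y[:n_ci] += coef * factor_ci[factor]
            explained_ci += coef**2
        for conn, coef in noise_coefs.items():
            y[:n_ci] += coef * mediator_noise[:n_ci, conn_lookup[conn]]
            explained_ci += coef**2
        y += spec.general_reading_coef * g
        explained_ci += spec.general_reading_coef**2
        if explained_ci >= 1.0:
            raise ValueError(f"infeasible effect sizes for subtest {subtest}")
        y[:n_ci] += np.sqrt(1.0 - explained_ci) * rng.standard_normal(n_ci)
        # TH: reading tracks chronological age
        explained_th = spec.th_age_coef**2 + spec.general_reading_coef**2
        if explained_th >= 1.0:
            raise ValueError("infeasible TH effect sizes")
        y[n_ci:] += spec.th_age_coef * z3[n_ci:]
        y[n_ci:] += np.sqrt(1.0 - explained_th) * rng.standard_normal(n_th)
        # group offsets add between-group variance; shrink the within-group
        # part so the population SD stays at score_sd
        w_ci, w_th = n_ci / n, n_th / n
        mean_off = w_ci * spec.ci_offset_sd + w_th * spec.th_offset_sd
        var_off = (
            w_ci * (spec.ci_offset_sd - mean_off) ** 2
            + w_th * (spec.th_offset_sd - mean_off) ** 2
        )
        if var_off >= 1.0:
            raise ValueError("group offsets alone exceed the score variance")
        y = np.sqrt(1.0 - var_off) * y
        y += np.where(group == "CI", spec.ci_offset_sd, spec.th_offset_sd) - mean_off
        scores = spec.score_mean + spec.score_sd * y
        reading[subtest] = np.clip(scores, spec.score_min, spec.score_max)

    truth = {
        "factors_ci": factor_ci,
        "effects": list(spec.mediation_effects),
        "connections": connections,
        "general_reading": g,
    }
    return {
        "clinical": clinical,
        "reading": reading,
        "connectivity": connectivity,
        "truth": truth,
    }
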