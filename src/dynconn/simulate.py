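"""Synthetic rs-fMRI cohort generator.

Emulates the statistical structure the dynamic-connectivity analysis assumes:
a two-group elderly cohort (subjective cognitive decline vs normal controls),
band-limited BOLD-like ROI series with slowly modulated amplitude envelopes
and network-structured shared signals, demographic covariates, and clinical
rating-scale scores that can carry prescribed partial correlations with
regional dynamics.

Generative model per subject i and ROI r::

    x(t) = a_ir(t) * s_ir(t) + L_r * g_i,net(r)(t) + edge terms + sigma_eps * eps(t)

where ``s`` and the per-network factors ``g`` are independent white noise
band-limited to 0.01-0.08 Hz and scaled to unit variance, and the amplitude
envelope is ``a(t) = a0 * (1 + m * sin(2*pi*f_slow*t + phi))`` with
``f_slow`` chosen commensurate with the sliding-window grid (period 375 s,
one full cycle across the 15 window centres) so the across-window envelope
variance is independent of the random phase.  Group
effects enter as shifts of the envelope baseline ``a0`` (dynamic-amplitude
mean effects), of the modulation depth ``m`` (dynamic-amplitude variance
effects), or of edge-level shared-signal loadings and gating rates (dynamic
connectivity effects).  Effect sizes ``d`` are in units of the between-subject
standard deviation of the shifted parameter.

The default parameterization reproduces the study conditions the pipeline is
designed for: 40 + 45 subjects, 200 volumes at TR = 2.5 s, a 300-ROI atlas
with 27 undefined-network ROIs, amplitude effects at the ROIs reported with
group differences, and clinical correlation targets matching the published
partial-correlation grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import ParcellationAtlas, UNDEFINED_NETWORK
from .cohort import CLINICAL_SCORES, CohortDataset, RoiTimeSeries

# ---------------------------------------------------------------------------
# Reference cohort statistics (per-group mean, sd) and score bounds used to
# scale simulated phenotypes: {score: (scd_mean, scd_sd, nc_mean, nc_sd)}.
# ---------------------------------------------------------------------------
SCORE_STATS: dict[str, tuple[float, float, float, float]] = {
    "AD8": (4.03, 1.82, 0.18, 0.39),
    "MMSE": (28.13, 1.45, 28.38, 1.81),
    "MoCA": (23.85, 3.29, 26.31, 3.52),
    "DSC": (53.18, 17.31, 60.31, 22.83),
    "DST-forward": (12.18, 2.34, 12.42, 2.24),
    "DST-backward": (6.21, 3.12, 7.36, 2.64),
    "LNS": (8.26, 2.55, 9.76, 3.19),
    "CF-animal": (16.05, 4.81, 19.18, 4.86),
    "CF-fruit": (13.26, 3.39, 14.11, 3.02),
    "CF-color": (12.21, 4.09, 14.33, 4.58),
    "CF-city": (18.23, 5.81, 20.02, 5.64),
    "FMT": (34.03, 4.06, 35.89, 4.80),
    "HADS-A": (5.40, 3.21, 2.84, 2.84),
    "HADS-D": (5.45, 3.36, 2.80, 3.29),
}

#: 13 named resting-state networks of the synthetic atlas.
NETWORK_NAMES = ["DMN", "SMd", "SMl", "AUD", "DAN", "SAL", "VIS", "FPN",
                 "VAN", "PMN", "MTL", "REW", "CON"]

#: roi_id block boundaries (inclusive start, inclusive end, network).
_NETWORK_BLOCKS = [
    (1, 40, "DMN"), (41, 60, "SMd"), (61, 70, "SMl"), (71, 90, "AUD"),
    (91, 110, "DAN"), (111, 140, "SAL"), (141, 170, "VIS"), (171, 200, "FPN"),
    (201, 220, "VAN"), (221, 230, "PMN"), (231, 240, "MTL"), (241, 250, "REW"),
    (251, 273, "CON"), (274, 300, UNDEFINED_NETWORK),
]

#: Anatomical labels for ROIs referenced in the clinical correlation grid.
_NAMED_ROIS = {
    75: ("left", "left STG"), 159: ("right", "right calcarine"),
    164: ("right", "right lingual gyrus"), 194: ("right", "right IPL"),
    211: ("right", "right MTG"), 260: ("right", "right pallidum"),
}


def make_synthetic_atlas(n_defined: int = 273, n_undefined: int = 27) -> ParcellationAtlas:
    """Build the synthetic 300-ROI parcellation (13 networks + undefined).

    This is a synthetic stand-in for a published volumetric parcellation: ROI
    ids, network block structure and the handful of anatomically named ROIs
    match the layout the analysis expects, while centroid coordinates are
    deterministic pseudo-random MNI-like positions.  Smaller atlases (for
    fast tests) keep the same proportional block structure.
    """
    n_total = n_defined + n_undefined
    if n_defined == 273 and n_undefined == 27:
        networks = np.empty(n_total, dtype=object)
        for lo, hi, net in _NETWORK_BLOCKS:
            networks[lo - 1:hi] = net
    else:
        # proportional assignment: cycle defined networks, undefined at the end
        reps = int(np.ceil(n_defined / len(NETWORK_NAMES)))
        networks = np.array(
            [NETWORK_NAMES[i % len(NETWORK_NAMES)] for i in range(n_defined)]
            + [UNDEFINED_NETWORK] * n_undefined, dtype=object)
        networks[:n_defined].sort()
    roi_ids = np.arange(1, n_total + 1)
    rng = np.random.default_rng(300273)  # atlas geometry is fixed, not spec-seeded
    coords = np.round(rng.uniform([-70, -100, -60], [70, 70, 80], size=(n_total, 3)), 1)
    hemi = np.where(coords[:, 0] < -3, "left", np.where(coords[:, 0] > 3, "right", "midline"))
    anatomy = np.array([f"{h} region {i}" for h, i in zip(hemi, roi_ids)], dtype=object)
    for rid, (h, label) in _NAMED_ROIS.items():
        if rid <= n_total:
            idx = rid - 1
            hemi[idx] = h
            anatomy[idx] = label
            coords[idx, 0] = abs(coords[idx, 0]) * (1 if h == "right" else -1)
    return ParcellationAtlas(pd.DataFrame({
        "roi_id": roi_ids, "network": networks, "anatomy": anatomy,
        "hemisphere": hemi, "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
    }))


@dataclass(frozen=True)
class AmplitudeEffect:
    """Group effect on local dynamics at one ROI.

    ``metric`` is "mean" (shifts the envelope baseline a0 of SCD subjects by
    d between-subject SDs) or "var" (shifts the modulation depth m likewise).
    ``d`` is signed: negative = lower in SCD.
    """
    roi_id: int
    metric: str
    d: float


@dataclass(frozen=True)
class DfcEffect:
    """Group effect on one seed-target coupling.

    ``metric`` "mean": the shared-signal loading of the edge is shifted by
    ``d`` between-subject SDs in SCD.  ``metric`` "var": the shared signal is
    gated on/off across the scan and SCD subjects switch at a rate scaled by
    (1 + d/2), destabilising the windowed correlation.
    """
    seed: int
    target: int
    metric: str
    d: float


@dataclass(frozen=True)
class CorrelationTarget:
    """Prescribed partial correlation between a regional metric and a score."""
    roi_id: int
    metric: str
    score: str
    rho: float


def default_amplitude_effects() -> list[AmplitudeEffect]:
    """Qualitative group-difference map: FPN mean decrease, VAN/VIS mean
    increases, AUD/VIS/VAN/CON variance increases."""
    return [
        AmplitudeEffect(194, "mean", -1.2),   # right IPL, FPN
        AmplitudeEffect(211, "mean", +1.2),   # right MTG, VAN
        AmplitudeEffect(159, "mean", +1.2),   # right calcarine, VIS
        AmplitudeEffect(75, "var", +1.2),     # left STG, AUD
        AmplitudeEffect(164, "var", +1.2),    # right lingual, VIS
        AmplitudeEffect(211, "var", +1.2),    # right MTG, VAN
        AmplitudeEffect(260, "var", +1.2),    # right pallidum, CON
    ]


def default_dfc_effects() -> list[DfcEffect]:
    """Weakened and destabilised coupling seeded from the FPN effect ROI."""
    return [
        DfcEffect(194, 15, "mean", -1.0),     # FPN seed to a DMN target
        DfcEffect(194, 115, "var", +1.0),     # FPN seed to a SAL target
    ]


def default_correlation_targets() -> list[CorrelationTarget]:
    """Published significant cells of the clinical correlation grid."""
    return [
        CorrelationTarget(194, "mean", "AD8", -0.29),
        CorrelationTarget(211, "mean", "AD8", 0.30),
        CorrelationTarget(159, "mean", "AD8", 0.38),
        CorrelationTarget(75, "var", "AD8", 0.51),
        CorrelationTarget(164, "var", "AD8", 0.42),
        CorrelationTarget(211, "var", "AD8", 0.32),
        CorrelationTarget(194, "mean", "MMSE", 0.29),
        CorrelationTarget(194, "mean", "CF-fruit", 0.32),
        CorrelationTarget(211, "var", "HADS-A", 0.33),
    ]


@dataclass(frozen=True)
class SimulationSpec:
    """All knobs of the synthetic cohort.

    Defaults are the study conditions: 40 SCD + 45 NC subjects, 200 volumes
    at TR 2.5 s, 273 analysis ROIs plus 27 undefined.  Noise and envelope
    parameters (documented in the methods note) are chosen so that windowed
    amplitude estimates are dominated by true between-subject spread rather
    than estimation noise, as expected for ROI-averaged BOLD.
    """

    n_scd: int = 40
    n_nc: int = 45
    n_roi_defined: int = 273
    n_roi_undefined: int = 27
    T: int = 200
    tr: float = 2.5
    amplitude_effects: tuple[AmplitudeEffect, ...] = field(
        default_factory=lambda: tuple(default_amplitude_effects()))
    dfc_effects: tuple[DfcEffect, ...] = field(
        default_factory=lambda: tuple(default_dfc_effects()))
    correlation_targets: tuple[CorrelationTarget, ...] = field(
        default_factory=lambda: tuple(default_correlation_targets()))
    signal_band: tuple[float, float] = (0.01, 0.08)
    f_slow: float = 1.0 / 375.0    # Hz, envelope period = window-centre span + step
    a0_mean: float = 1.0           # envelope baseline
    a0_sd: float = 0.18            # between-subject SD of a0
    m_mean: float = 0.45           # modulation depth
    m_sd: float = 0.35             # between-subject SD of m
    m_max: float = 1.4             # modulation-depth ceiling
    network_loading: float = 0.3   # shared network-factor loading
    edge_loading: float = 0.8      # shared-signal loading for dfc effect edges
    edge_loading_sd: float = 0.2   # between-subject SD of the edge loading
    gate_rate: float = 4.0         # mean on/off switches per scan (dfc var)
    noise_sd: float = 0.3          # broadband sensor/physiological noise
    confound_age: bool = False     # couple a0 to age to exercise adjustment
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_scd, self.n_nc, self.n_roi_defined, self.T) <= 0:
            raise ValueError("counts must be positive")
        for t in self.correlation_targets:
            if abs(t.rho) >= 1:
                raise ValueError(f"|target rho| must be < 1, got {t.rho}")
        for e in self.amplitude_effects + tuple(self.dfc_effects):
            if not np.isfinite(e.d):
                raise ValueError("effect sizes must be finite")

    @property
    def n_subjects(self) -> int:
        return self.n_scd + self.n_nc


def simulate_phenotypes(spec: SimulationSpec,
                        rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Draw the phenotype table: demographics, motion, clinical scores.

    Age ~ N(65.5, 5.7^2) truncated at 50; education ~ N(10.1, 4.2^2)
    truncated at 0; P(female) = 0.58; mean FD ~ |N(0.15, 0.07^2)| capped at
    0.5 mm.  AD8 is drawn per group (SCD in [2, 8], NC in [0, 1], integer) —
    the subjective-complaint score defines group membership.  Other scales
    are drawn from the per-group reference means/SDs and clipped to their
    printed ranges.
    """
    rng = np.random.default_rng(rng if rng is not None else spec.seed)
    n = spec.n_subjects
    group = np.array(["SCD"] * spec.n_scd + ["NC"] * spec.n_nc)
    is_scd = group == "SCD"

    age = rng.normal(65.5, 5.7, n)
    while (age < 50).any():
        age[age < 50] = rng.normal(65.5, 5.7, int((age < 50).sum()))
    education = np.maximum(rng.normal(10.1, 4.2, n), 0.0)
    sex = np.where(rng.random(n) < 0.58, "female", "male")
    mean_fd = np.minimum(np.abs(rng.normal(0.15, 0.07, n)), 0.5)

    pheno = pd.DataFrame({
        "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
        "group": group,
        "age": np.round(age, 2),
        "sex": sex,
        "education": np.round(education, 2),
        "mean_fd": np.round(mean_fd, 4),
    })
    for score in CLINICAL_SCORES:
        ms, ss, mn, sn = SCORE_STATS[score]
        vals = np.where(is_scd, rng.normal(ms, ss, n), rng.normal(mn, sn, n))
        if score == "AD8":
            vals = np.round(np.where(is_scd, np.clip(vals, 2, 8), np.clip(vals, 0, 1)))
        else:
            from .cohort import SCORE_RANGES
            lo, hi = SCORE_RANGES[score]
            vals = np.clip(vals, lo, hi if hi is not None else np.inf)
        pheno[score] = np.round(vals, 2)
    return pheno


def _bandlimited_noise(rng: np.random.Generator, shape: tuple[int, ...],
                       T: int, tr: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-variance white noise brick-wall filtered to ``band`` (Hz)."""
    white = rng.standard_normal(shape + (T,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(T, d=tr)
    spec[..., (freqs < band[0]) | (freqs > band[1])] = 0.0
    x = np.fft.irfft(spec, n=T, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _telegraph_gate(rng: np.random.Generator, T: int, tr: float, rate: float) -> np.ndarray:
    """Random on/off gate with on average ``rate`` switches per scan."""
    p_switch = min(rate / max(T - 1, 1), 1.0)
    flips = rng.random(T - 1) < p_switch
    state = np.empty(T, dtype=float)
    state[0] = float(rng.random() < 0.5)
    for t in range(1, T):
        state[t] = 1.0 - state[t - 1] if flips[t - 1] else state[t - 1]
    return state


def simulate_timeseries(spec: SimulationSpec, phenotypes: pd.DataFrame,
                        atlas: ParcellationAtlas | None = None,
                        rng: np.random.Generator | int | None = None
                        ) -> dict[str, RoiTimeSeries]:
    """Simulate one units x time matrix per subject (unit = atlas ROI).

    See the module docstring for the generative model.  Effects referencing a
    ROI absent from the atlas raise.
    """
    rng = np.random.default_rng(rng if rng is not None else spec.seed)
    atlas = atlas or make_synthetic_atlas(spec.n_roi_defined, spec.n_roi_undefined)
    roi_ids = atlas.roi_ids
    id_to_pos = {rid: i for i, rid in enumerate(roi_ids)}
    for eff in spec.amplitude_effects:
        if eff.roi_id not in id_to_pos:
            raise ValueError(f"amplitude effect ROI {eff.roi_id} not in atlas")
    for eff in spec.dfc_effects:
        for rid in (eff.seed, eff.target):
            if rid not in id_to_pos:
                raise ValueError(f"dFC effect ROI {rid} not in atlas")

    S, R, T, tr = spec.n_subjects, len(roi_ids), spec.T, spec.tr
    is_scd = (phenotypes["group"] == "SCD").to_numpy()
    t_sec = np.arange(T) * tr

    # private band-limited signals and network factors
    s_priv = _bandlimited_noise(rng, (S, R), T, tr, spec.signal_band)
    nets = atlas.table["network"].to_numpy()
    net_names = list(pd.unique(nets))
    net_idx = np.array([net_names.index(nm) for nm in nets])
    g = _bandlimited_noise(rng, (S, len(net_names)), T, tr, spec.signal_band)

    # envelope parameters with group effects
    a0 = spec.a0_mean + spec.a0_sd * rng.standard_normal((S, R))
    m = spec.m_mean + spec.m_sd * rng.standard_normal((S, R))
    if spec.confound_age:
        age_z = ((phenotypes["age"] - phenotypes["age"].mean())
                 / phenotypes["age"].std()).to_numpy()
        a0 += 0.5 * spec.a0_sd * age_z[:, None]
    for eff in spec.amplitude_effects:
        pos = id_to_pos[eff.roi_id]
        if eff.metric == "mean":
            a0[is_scd, pos] += eff.d * spec.a0_sd
        elif eff.metric == "var":
            m[is_scd, pos] += eff.d * spec.m_sd
        else:
            raise ValueError(f"unknown amplitude metric {eff.metric!r}")
    a0 = np.maximum(a0, 0.05)
    m = np.clip(m, 0.0, spec.m_max)

    phi = rng.uniform(0, 2 * np.pi, (S, R))
    # The envelope is normalised so that shifting the modulation depth m moves
    # the across-window amplitude variance without shifting the across-window
    # amplitude mean: the correction sqrt(1 + c2 m^2 + c4 m^4) cancels the
    # within-window amplitude excess of a modulated band-limited carrier for
    # the canonical 50-TR window (leading term (1 - sinc^2)/2; coefficients
    # calibrated against the windowed amplitude statistics).
    c2, c4 = 0.1285, 0.0634
    msq = m[:, :, None] ** 2
    mean_norm = np.sqrt(1.0 + c2 * msq + c4 * msq ** 2)
    envelope = a0[:, :, None] * (
        1.0 + m[:, :, None] * np.sin(2 * np.pi * spec.f_slow * t_sec + phi[:, :, None])
    ) / mean_norm

    x = envelope * s_priv
    x += spec.network_loading * g[np.arange(S)[:, None], net_idx[None, :], :]

    # edge-level coupling effects
    for eff in spec.dfc_effects:
        ps, pt = id_to_pos[eff.seed], id_to_pos[eff.target]
        shared = _bandlimited_noise(rng, (S,), T, tr, spec.signal_band)
        lam = spec.edge_loading + spec.edge_loading_sd * rng.standard_normal(S)
        if eff.metric == "mean":
            lam[is_scd] += eff.d * spec.edge_loading_sd
            contrib = lam[:, None] * shared
        elif eff.metric == "var":
            rates = np.where(is_scd, spec.gate_rate * (1 + eff.d / 2), spec.gate_rate)
            gates = np.stack([_telegraph_gate(rng, T, tr, r) for r in rates])
            contrib = lam[:, None] * gates * shared
        else:
            raise ValueError(f"unknown dFC metric {eff.metric!r}")
        lam = np.maximum(lam, 0.0)
        x[:, ps, :] += contrib
        x[:, pt, :] += contrib

    x += spec.noise_sd * rng.standard_normal((S, R, T))

    return {
        sid: RoiTimeSeries(sid, x[i], tr, unit_roi_ids=roi_ids)
        for i, sid in enumerate(phenotypes["subject_id"])
    }


def generate_clinical_scores(spec: SimulationSpec, phenotypes: pd.DataFrame,
                             mdalff: pd.DataFrame,
                             rng: np.random.Generator | int | None = None
                             ) -> pd.DataFrame:
    """Rewrite targeted clinical scores to carry prescribed partial correlations.

    For each target (roi, metric, score, rho) the regional metric is
    residualized against the GLM covariates and standardized to ``u``; the
    score's standardized part is ``rho * u + sqrt(1 - rho^2) * noise``.  When
    several targets address the same score the mixing weights solve
    ``w = Rinv rho`` (R = correlation matrix of the residualized metrics) so
    every prescribed cell is hit simultaneously; the residual variance is
    ``1 - rho' Rinv rho`` (scaled down with a warning if the targets are
    jointly infeasible).  Scores are rescaled to the per-group reference
    mean/SD and clipped to their printed ranges, which attenuates extreme
    targets; the construction is calibrated for |rho| <= 0.6.
    """
    from .stats import encode_sex

    rng = np.random.default_rng(rng if rng is not None else spec.seed)
    pheno = phenotypes.copy()
    n = len(pheno)
    C = np.column_stack([
        pheno["age"].to_numpy(float), encode_sex(pheno["sex"]),
        pheno["education"].to_numpy(float), pheno["mean_fd"].to_numpy(float)])
    X = np.column_stack([np.ones(n), C])
    proj = np.eye(n) - X @ np.linalg.pinv(X)

    by_score: dict[str, list[CorrelationTarget]] = {}
    for tgt in spec.correlation_targets:
        if abs(tgt.rho) >= 1:
            raise ValueError(f"|target rho| must be < 1, got {tgt.rho}")
        by_score.setdefault(tgt.score, []).append(tgt)

    wide = {metric: mdalff.pivot(index="subject_id", columns="roi_id",
                                 values=f"mdalff_{metric}").loc[pheno["subject_id"]]
            for metric in ("mean", "var")}
    is_scd = (pheno["group"] == "SCD").to_numpy()

    for score, targets in by_score.items():
        U = np.column_stack([
            proj @ wide[t.metric][t.roi_id].to_numpy(float) for t in targets])
        U = (U - U.mean(axis=0)) / U.std(axis=0)
        rho = np.array([t.rho for t in targets])
        Rcorr = np.corrcoef(U, rowvar=False) if U.shape[1] > 1 else np.ones((1, 1))
        w = np.linalg.solve(Rcorr, rho)
        resid_var = 1.0 - float(rho @ w)
        if resid_var < 0:
            import warnings
            warnings.warn(f"correlation targets for {score} jointly infeasible; "
                          "scaling weights down")
            w *= np.sqrt(0.99 / float(rho @ w))
            resid_var = 0.01
        z = U @ w + np.sqrt(resid_var) * (proj @ rng.standard_normal(n))
        z = (z - z.mean()) / z.std()

        ms, ss, mn, sn = SCORE_STATS[score]
        vals = np.where(is_scd, ms + ss * z, mn + sn * z)
        from .cohort import SCORE_RANGES
        lo, hi = SCORE_RANGES[score]
        vals = np.clip(vals, lo, hi if hi is not None else np.inf)
        if score == "AD8":
            vals = np.round(np.where(is_scd, np.clip(vals, 2, 8), np.clip(vals, 0, 1)))
        pheno[score] = np.round(vals, 2)
    return pheno


def simulate_cohort(spec: SimulationSpec = SimulationSpec(),
                    rng: np.random.Generator | int | None = None,
                    update_scores: bool = True) -> CohortDataset:
    """Full synthetic cohort: atlas, phenotypes, time series (and, when
    ``update_scores`` is set, clinical scores rewritten to carry the spec's
    correlation targets, which requires one mdALFF pass).

    Deterministic: the same spec and seed reproduce the cohort bit-for-bit.
    """
    rng = np.random.default_rng(rng if rng is not None else spec.seed)
    atlas = make_synthetic_atlas(spec.n_roi_defined, spec.n_roi_undefined)
    pheno = simulate_phenotypes(spec, rng)
    series = simulate_timeseries(spec, pheno, atlas, rng)
    dataset = CohortDataset(atlas=atlas, phenotypes=pheno, series=series)
    if update_scores and spec.correlation_targets:
        from .atlas import filter_defined_networks
        from .conditioning import condition_series
        from .metrics import WindowSpec, compute_mdalff

        analysis_atlas = filter_defined_networks(atlas)
        parts = []
        for sid in pheno["subject_id"]:
            cond = condition_series(series[sid])
            parts.append(compute_mdalff(cond, analysis_atlas, WindowSpec()))
        mdalff = pd.concat(parts, ignore_index=True)
        dataset.phenotypes = generate_clinical_scores(spec, pheno, mdalff, rng)
    dataset.validate()
    return dataset
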