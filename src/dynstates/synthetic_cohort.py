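"""Synthetic cohorts with known dynamic and behavioural ground truth.

The analysis pipeline assumes that parcellated resting-state fMRI
signals are narrow-band oscillations whose phase relations switch among
a small number of recurrent regimes, that a superordinate personality
trait (emotional instability) modulates the link between those dynamics
and clinical outcome, and that white-matter diffusion tables carry a
low-rank group effect.  This module generates data with exactly that
structure so every downstream stage can be validated against a planted
truth.

The generative model for the time courses: each subject carries a
hidden Markov chain over ``k_true`` regimes; each regime is a signed
bipartition of the components (a small "minority" community in
anti-phase with the rest); every component emits a sinusoid at a
subject-specific carrier frequency inside the analysis band, phase
shifted by ``phase_offset_rad`` when its regime sign is negative, plus
white Gaussian observation noise.  Under this model the leading
eigenvector of the phase-coherence matrix reproduces the planted
bipartition exactly in the noiseless case, which is what makes
planted-regime recovery a meaningful oracle for the full pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "OutcomeBetas",
    "CohortData",
    "simulate_markov_sequence",
    "default_regime_signs",
    "default_markov_matrix",
    "simulate_ic_timecourses",
    "simulate_personality",
    "simulate_outcomes",
    "simulate_dti_rois",
    "simulate_cohort",
    "JHU_ROI_NAMES",
    "NEO_DIMENSIONS",
    "EMOTIONAL_INSTABILITY_LOADINGS",
]

NEO_DIMENSIONS = (
    "neuroticism",
    "extraversion",
    "openness",
    "agreeableness",
    "conscientiousness",
)

# Loading pattern of the emotional-instability superordinate trait:
# high Neuroticism, moderate Openness, low Extraversion, Agreeableness
# and Conscientiousness.  Order follows NEO_DIMENSIONS.
EMOTIONAL_INSTABILITY_LOADINGS = np.array([0.77, -0.45, 0.33, -0.13, -0.28])

# Plausible NEO-FFI dimension-total locations and spreads used to map
# the latent trait onto instrument-scale scores.
_NEO_MEANS = np.array([29.0, 40.0, 36.0, 44.0, 45.0])
_NEO_SDS = np.array([7.0, 5.5, 5.0, 4.5, 5.5])

_MIDLINE_ROIS = ("genu_cc", "body_cc", "splenium_cc", "fornix")
_BILATERAL_ROIS = (
    "anterior_corona_radiata",
    "superior_corona_radiata",
    "posterior_corona_radiata",
    "anterior_limb_internal_capsule",
    "posterior_limb_internal_capsule",
    "retrolenticular_internal_capsule",
    "external_capsule",
    "cingulum_cingulate_gyrus",
    "cingulum_hippocampus",
    "fornix_stria_terminalis",
    "superior_longitudinal_fasciculus",
    "superior_fronto_occipital_fasciculus",
    "posterior_thalamic_radiation",
    "sagittal_stratum",
    "uncinate_fasciculus",
    "corticospinal_tract",
    "cerebral_peduncle",
    "superior_cerebellar_peduncle",
    "inferior_cerebellar_peduncle",
    "medial_lemniscus",
    "tapetum",
)

#: 46 white-matter skeleton ROI labels (JHU-atlas style): 4 midline
#: structures plus 21 bilateral tract pairs.
JHU_ROI_NAMES: tuple[str, ...] = _MIDLINE_ROIS + tuple(
    f"{name}_{side}" for name in _BILATERAL_ROIS for side in ("l", "r")
)

#: ROIs carrying the planted group effect in the diffusion generator.
DEFAULT_AFFECTED_ROIS = (
    "fornix",
    "genu_cc",
    "anterior_corona_radiata_l",
    "anterior_corona_radiata_r",
    "posterior_corona_radiata_l",
    "posterior_corona_radiata_r",
)


def _validate_stochastic(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(p < 0):
        raise ValueError("transition matrix has negative entries")
    if np.max(np.abs(p.sum(axis=1) - 1.0)) > 1e-12:
        raise ValueError("transition-matrix rows must sum to 1 (within 1e-12)")
    return p


def simulate_markov_sequence(
    p: np.ndarray,
    t: int,
    init: np.ndarray | int | None = None,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Sample a label sequence (values ``1..k``) from a Markov chain.

    Parameters
    ----------
    p
        Row-stochastic ``k x k`` transition matrix.
    t
        Sequence length, at least 1.
    init
        Either an initial distribution over the ``k`` states, a 1-based
        initial state label, or ``None`` for the uniform distribution.
    seed
        Integer seed or a ``numpy`` generator.
    """
    p = _validate_stochastic(p)
    if t < 1:
        raise ValueError("sequence length must be >= 1")
    k = p.shape[0]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if init is None:
        dist = np.full(k, 1.0 / k)
    elif np.isscalar(init):
        state = int(init)
        if not 1 <= state <= k:
            raise ValueError(f"initial state must be in 1..{k}")
        dist = np.zeros(k)
        dist[state - 1] = 1.0
    else:
        dist = np.asarray(init, dtype=float)
        if dist.shape != (k,) or np.any(dist < 0) or abs(dist.sum() - 1.0) > 1e-12:
            raise ValueError("init must be a probability distribution of length k")
    seq = np.empty(t, dtype=np.int64)
    seq[0] = rng.choice(k, p=dist)
    for i in range(1, t):
        seq[i] = rng.choice(k, p=p[seq[i - 1]])
    return seq + 1


def default_regime_signs(
    k: int, n_components: int, rng: np.random.Generator
) -> np.ndarray:
    """Signed bipartitions emulating empirical phase-locking states.

    Each regime assigns a small minority community (8-13 components) the
    positive sign and the remainder the negative sign.  Keeping the
    minority below a quarter of the components guarantees that any two
    regime vectors have positive inner product, so sequential sign
    alignment of the eigenvector series preserves one orientation per
    regime across separated visits.
    """
    if k < 2:
        raise ValueError("need at least 2 regimes")
    max_minority = min(13, n_components // 4)
    min_minority = min(8, max(1, max_minority))
    signs = np.empty((k, n_components), dtype=np.int64)
    seen: set[bytes] = set()
    for r in range(k):
        while True:
            size = int(rng.integers(min_minority, max_minority + 1))
            members = rng.choice(n_components, size=size, replace=False)
            vec = -np.ones(n_components, dtype=np.int64)
            vec[members] = 1
            if vec.tobytes() not in seen:
                seen.add(vec.tobytes())
                signs[r] = vec
                break
    return signs


def default_markov_matrix(k: int, p_stay: float = 0.985) -> np.ndarray:
    """Sticky uniform chain: ``p_stay`` on the diagonal, rest uniform.

    The default stay probability is set by the temporal resolution of
    the analysis band: a 0.04-0.07 Hz band-pass smears each regime
    switch over roughly +/-4 volumes (about 2.6 misassigned volumes per
    switch), so the switch rate must stay below ~0.015 per volume for
    boundary contamination to remain under ~4% of timepoints.  The
    default mean dwell of ~67 volumes (107 s at TR 1.6 s) keeps the
    planted regimes resolvable; it is deliberately long compared with
    empirical fMRI state durations, because the generator is an
    identifiability benchmark, not a fit to real dynamics.
    """
    if not 0.0 < p_stay < 1.0:
        raise ValueError("p_stay must be in (0, 1)")
    p = np.full((k, k), (1.0 - p_stay) / (k - 1))
    np.fill_diagonal(p, p_stay)
    return p


@dataclass
class SimulationConfig:
    """Parameters of the synthetic fMRI cohort generator."""

    n_subjects_per_group: int = 10
    n_components: int = 53
    n_volumes: int = 400
    tr_seconds: float = 1.6
    band: tuple[float, float] = (0.04, 0.07)
    k_true: int = 5
    regime_signs: np.ndarray | None = None
    markov_p: np.ndarray | None = None
    phase_offset_rad: float = np.pi
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 2:
            raise ValueError("k_true must be >= 2")
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group must be >= 1")
        nyq = 1.0 / (2.0 * self.tr_seconds)
        low, high = self.band
        if not 0.0 < low < high < nyq:
            raise ValueError(f"band must lie inside (0, Nyquist = {nyq:.4g})")
        if self.markov_p is not None:
            p = _validate_stochastic(self.markov_p)
            if p.shape[0] != self.k_true:
                raise ValueError("markov_p must be k_true x k_true")
        if self.regime_signs is not None:
            s = np.asarray(self.regime_signs)
            if s.shape != (self.k_true, self.n_components):
                raise ValueError("regime_signs must be k_true x n_components")
            if not np.all(np.isin(s, (-1, 1))):
                raise ValueError("regime_signs entries must be +/-1")
            if np.any(np.all(s == s[:, :1], axis=1)):
                raise ValueError("each regime must contain both signs")

    @classmethod
    def recovery_benchmark(cls, seed: int = 0) -> "SimulationConfig":
        """Conditions of the planted-state recovery benchmark.

        20 subjects (10 per group), 300 volumes, 53 components, 5
        regimes, observation-noise SD 0.3.
        """
        return cls(
            n_subjects_per_group=10,
            n_volumes=300,
            noise_sd=0.3,
            seed=seed,
        )


@dataclass
class OutcomeBetas:
    """Coefficients of the synthetic outcome model.

    The linear predictor for six-month symptom severity is
    ``intercept + ei * EI + metric * M + interaction * EI * M`` plus
    small covariate effects and Gaussian noise, where EI is the true
    emotional-instability latent and M the standardised state metric.
    The negative default interaction plants the protective effect of
    state visits in emotionally unstable subjects.
    """

    intercept: float = 12.0
    ei: float = 4.0
    metric: float = -2.0
    interaction: float = -3.0
    age: float = 0.05
    sex: float = 0.5
    education: float = -0.3
    noise_sd: float = 2.5
    outcome_scale: float = 0.25  # logistic scale for dichotomous recovery


@dataclass
class SyntheticTruth:
    """Ground truth serialised alongside every generated dataset."""

    seed: int
    regime_sequences: dict[str, np.ndarray] = field(default_factory=dict)
    regime_signs: np.ndarray | None = None
    markov_p: np.ndarray | None = None
    carrier_hz: dict[str, float] = field(default_factory=dict)
    emotional_instability: dict[str, float] = field(default_factory=dict)
    outcome_betas: OutcomeBetas | None = None
    dti_affected_weights: np.ndarray | None = None
    dti_shift: float = 0.0

    def to_jsonable(self) -> dict:
        return {
            "seed": self.seed,
            "regime_sequences": {
                k: v.tolist() for k, v in self.regime_sequences.items()
            },
            "regime_signs": None
            if self.regime_signs is None
            else self.regime_signs.tolist(),
            "markov_p": None if self.markov_p is None else self.markov_p.tolist(),
            "carrier_hz": dict(self.carrier_hz),
            "emotional_instability": dict(self.emotional_instability),
            "outcome_betas": None
            if self.outcome_betas is None
            else vars(self.outcome_betas),
            "dti_affected_weights": None
            if self.dti_affected_weights is None
            else self.dti_affected_weights.tolist(),
            "dti_shift": self.dti_shift,
        }


def _subject_ids(n: int) -> list[str]:
    return [f"sub-{i + 1:03d}" for i in range(n)]


def simulate_ic_timecourses(
    cfg: SimulationConfig,
) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Generate per-subject component time courses with planted regimes.

    Returns a mapping ``subject_id -> (n_volumes, n_components)``
    DataFrame and the :class:`SyntheticTruth` holding each subject's
    regime sequence, the regime sign vectors, the transition matrix and
    the carrier frequencies.
    """
    rng = np.random.default_rng(cfg.seed)
    signs = (
        np.asarray(cfg.regime_signs)
        if cfg.regime_signs is not None
        else default_regime_signs(cfg.k_true, cfg.n_components, rng)
    )
    markov_p = (
        np.asarray(cfg.markov_p, dtype=float)
        if cfg.markov_p is not None
        else default_markov_matrix(cfg.k_true)
    )
    truth = SyntheticTruth(
        seed=cfg.seed, regime_signs=signs, markov_p=markov_p
    )
    n_total = 2 * cfg.n_subjects_per_group
    columns = [f"ic{j + 1:02d}" for j in range(cfg.n_components)]
    t_seconds = np.arange(cfg.n_volumes) * cfg.tr_seconds
    data: dict[str, pd.DataFrame] = {}
    for sid in _subject_ids(n_total):
        # Carrier strictly inside the passband so filtering is near
        # transparent; one carrier and global phase per subject.
        f = rng.uniform(0.045, 0.065)
        phi0 = rng.uniform(0.0, 2.0 * np.pi)
        seq = simulate_markov_sequence(markov_p, cfg.n_volumes, seed=rng)
        offsets = np.where(signs[seq - 1] == -1, cfg.phase_offset_rad, 0.0)
        base = 2.0 * np.pi * f * t_seconds[:, None] + phi0
        x = np.sin(base + offsets)
        x += rng.normal(0.0, cfg.noise_sd, size=x.shape)
        data[sid] = pd.DataFrame(x, columns=columns)
        truth.regime_sequences[sid] = seq
        truth.carrier_hz[sid] = f
    return data, truth


def simulate_personality(
    n: int,
    loadings: np.ndarray | None = None,
    noise_sd: float = 0.5,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Big Five dimension totals driven by one latent trait.

    Each subject's five scores are ``loading * latent + noise`` in
    standardised units, then shifted and scaled into plausible NEO-FFI
    dimension-total ranges.  Returns the table and the true latent.
    """
    loadings = (
        EMOTIONAL_INSTABILITY_LOADINGS
        if loadings is None
        else np.asarray(loadings, dtype=float)
    )
    if loadings.shape != (5,):
        raise ValueError("loadings must have length 5")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    latent = rng.normal(size=n)
    z = latent[:, None] * loadings[None, :]
    if noise_sd > 0:
        z = z + rng.normal(0.0, noise_sd, size=z.shape)
    scores = _NEO_MEANS + _NEO_SDS * z
    return pd.DataFrame(scores, columns=list(NEO_DIMENSIONS)), latent


def simulate_outcomes(
    ei: np.ndarray,
    metric: np.ndarray,
    covariates: pd.DataFrame,
    betas: OutcomeBetas | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Six-month symptom severity (0-42) and dichotomous recovery.

    Severity is the rounded, clipped linear predictor with an
    EI-by-metric interaction; the binary outcome (1 = complete
    recovery) follows a logistic model on the negated predictor, so
    higher predicted severity means lower recovery probability.
    """
    betas = betas or OutcomeBetas()
    ei = np.asarray(ei, dtype=float)
    metric = np.asarray(metric, dtype=float)
    if not (len(ei) == len(metric) == len(covariates)):
        raise ValueError("ei, metric and covariates must have equal length")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    m_sd = metric.std()
    m = (metric - metric.mean()) / m_sd if m_sd > 0 else metric - metric.mean()
    lp = (
        betas.intercept
        + betas.ei * ei
        + betas.metric * m
        + betas.interaction * ei * m
        + betas.age * covariates["age"].to_numpy(dtype=float)
        + betas.sex * covariates["sex"].to_numpy(dtype=float)
        + betas.education * covariates["education"].to_numpy(dtype=float)
    )
    noisy = lp + (rng.normal(0.0, betas.noise_sd, size=len(ei)) if betas.noise_sd > 0 else 0.0)
    severity = np.clip(np.round(noisy), 0, 42).astype(np.int64)
    centred = noisy - np.median(noisy)
    p_recovery = 1.0 / (1.0 + np.exp(betas.outcome_scale * centred))
    outcome = (rng.uniform(size=len(ei)) < p_recovery).astype(np.int64)
    return severity, outcome


def simulate_dti_rois(
    n_per_group: int,
    n_rois: int = 46,
    affected_weights: np.ndarray | None = None,
    shift: float = 0.5,
    noise_sd: float = 0.3,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Subject x ROI diffusion table with a planted patient deficit.

    Subjects follow a one-factor model of white-matter integrity: a
    latent factor loads on every ROI but most strongly on the
    injury-vulnerable ROIs given by ``affected_weights`` (so the
    leading principal component of the z-scored table carries its
    highest coefficients there), plus idiosyncratic noise around
    FA-like baselines.  Patient rows are additionally shifted by
    ``-shift * affected_weights``.  Returns the table (with a
    ``group`` column, patients first) and the weight vector used.
    """
    if n_rois != len(JHU_ROI_NAMES):
        raise ValueError(
            f"n_rois must be {len(JHU_ROI_NAMES)} (skeleton parcellation)"
        )
    if affected_weights is None:
        affected_weights = np.zeros(n_rois)
        for name in DEFAULT_AFFECTED_ROIS:
            affected_weights[JHU_ROI_NAMES.index(name)] = 1.0
    else:
        affected_weights = np.asarray(affected_weights, dtype=float)
        if affected_weights.shape != (n_rois,):
            raise ValueError(f"affected_weights must have length {n_rois}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = 2 * n_per_group
    baseline = rng.uniform(0.35, 0.65, size=n_rois)
    # Factor loadings: a weak background on every ROI plus the full
    # weight on the vulnerable ROIs, in raw FA-scale units (x 0.05).
    peak = affected_weights.max()
    background = 0.15
    loadings = background + (
        (1.0 - background) * affected_weights / peak if peak > 0 else 0.0
    )
    integrity = rng.normal(size=n)
    values = (
        baseline
        + 0.05 * integrity[:, None] * loadings[None, :]
        + 0.05 * noise_sd * rng.normal(size=(n, n_rois))
    )
    values[:n_per_group] -= 0.05 * shift * affected_weights[None, :]
    table = pd.DataFrame(values, columns=list(JHU_ROI_NAMES))
    table.insert(0, "group", ["mtbi"] * n_per_group + ["hc"] * n_per_group)
    return table, affected_weights


@dataclass
class CohortData:
    """Everything one synthetic study run produces."""

    timecourses: dict[str, pd.DataFrame]
    cohort: pd.DataFrame
    dti: dict[str, pd.DataFrame]
    truth: SyntheticTruth


def _planted_state3_visits(seq: np.ndarray, state: int = 3) -> int:
    in_state = seq == state
    starts = in_state & ~np.concatenate(([False], in_state[:-1]))
    return int(starts.sum())


def simulate_cohort(
    cfg: SimulationConfig,
    betas: OutcomeBetas | None = None,
    dti_shift: float = 0.5,
) -> CohortData:
    """Full study dataset: time courses, cohort table, diffusion tables.

    The cohort table contains group, demographics, Big Five totals,
    symptom severity at baseline and six months, and the dichotomised
    functional outcome.  Severity is generated with an interaction
    between the true emotional-instability latent and the planted
    number of visits to regime 3, so the inferential stage has a known
    signal to recover.
    """
    betas = betas or OutcomeBetas()
    rng = np.random.default_rng(np.random.default_rng(cfg.seed).integers(2**31))
    tcs, truth = simulate_ic_timecourses(cfg)
    sids = list(tcs)
    n = len(sids)
    n_pat = cfg.n_subjects_per_group

    age = rng.integers(18, 71, size=n)
    sex = (rng.uniform(size=n) < 0.4).astype(np.int64)
    education = rng.choice(
        np.arange(1, 8), size=n, p=[0.02, 0.03, 0.10, 0.15, 0.25, 0.30, 0.15]
    )
    covariates = pd.DataFrame(
        {"age": age, "sex": sex, "education": education}, index=sids
    )

    bigfive, latent = simulate_personality(n, noise_sd=0.5, seed=rng)
    bigfive.index = sids
    truth.emotional_instability = dict(zip(sids, latent.tolist()))
    truth.outcome_betas = betas

    visits3 = np.array(
        [_planted_state3_visits(truth.regime_sequences[s]) for s in sids],
        dtype=float,
    )
    severity6, outcome = simulate_outcomes(
        latent, visits3, covariates, betas=betas, seed=rng
    )
    baseline_noise = rng.normal(0.0, betas.noise_sd, size=n)
    severity0 = np.clip(
        np.round(severity6 + 2.0 + baseline_noise), 0, 42
    ).astype(np.int64)

    cohort = pd.DataFrame(
        {
            "subject_id": sids,
            "group": ["mtbi"] * n_pat + ["hc"] * (n - n_pat),
            "age": age,
            "sex": sex,
            "education": education,
        }
    )
    for dim in NEO_DIMENSIONS:
        cohort[dim] = bigfive[dim].to_numpy()
    cohort["severity_baseline"] = severity0
    cohort["severity_6mo"] = severity6
    cohort["outcome_complete"] = outcome

    dti: dict[str, pd.DataFrame] = {}
    for metric in ("fa", "md", "rd", "ad"):
        # Only FA carries the planted group deficit; the other metrics
        # are null tables, mirroring a selective microstructural effect.
        metric_shift = dti_shift if metric == "fa" else 0.0
        table, weights = simulate_dti_rois(
            n_pat, shift=metric_shift, seed=rng
        )
        table.insert(0, "subject_id", sids[: 2 * n_pat])
        dti[metric] = table
        if metric == "fa":
            truth.dti_affected_weights = weights
            truth.dti_shift = dti_shift
    return CohortData(timecourses=tcs, cohort=cohort, dti=dti, truth=truth)
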