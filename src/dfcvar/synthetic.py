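"""Synthetic longitudinal two-group cohorts with controlled dFC structure.

The generator emulates the study design the pipeline targets: two patient
groups (treated TSZ, drug-only DSZ) scanned at baseline (t1) and after four
weeks (t2), plus a baseline-only healthy-control group.  BOLD-like signals
are produced by covariance-state switching: the inter-regional correlation
of designated region pairs flips between a low and a high level under a
hidden two-state Markov chain, so the windowed-correlation variability of a
pair is directly controlled by its switching rate.  The planted treatment
effect multiplies the switching rate of "responsive" pairs by
``effect_delta`` for treated subjects at t2 — fewer state transitions,
hence lower temporal variability I.

Region pairs live on disjoint two-region blocks (regions 2k and 2k+1 form
block k); inter-block correlations are zero.  This keeps every instantaneous
covariance trivially positive definite and makes the ground truth per pair
exact.  Symptom scores are PANSS-like: the per-subject negative-subscale
remission ratio is a linear function of the subject's realized relative
variability drop on the responsive pairs plus Gaussian noise, so
brain-behavior correlation and SVR response prediction have a planted,
recoverable signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dfcvar.core_io import COHORT_COLUMNS, RoiTimeSeries
from dfcvar.prep import bandpass
from dfcvar.variability import WindowScheme, roi_variability_matrix

#: plausible clinical score ranges (positive/negative 7-49, general 16-112)
PANSS_BOUNDS = {"positive": (7, 49), "negative": (7, 49), "general": (16, 112)}


@dataclass
class StateModel:
    """Hidden-state covariance-switching model for one region set.

    Each state carries an R x R correlation matrix (unit diagonal, PSD);
    the active state evolves as a Markov chain with the given row-stochastic
    transition matrix.
    """

    covariances: list[np.ndarray]
    transition: np.ndarray

    def __post_init__(self) -> None:
        self.covariances = [np.asarray(c, dtype=np.float64) for c in self.covariances]
        self.transition = np.asarray(self.transition, dtype=np.float64)
        n = self.n_states
        if self.transition.shape != (n, n):
            raise ValueError("transition must be n_states x n_states")
        if np.any(self.transition < 0) or not np.allclose(self.transition.sum(axis=1), 1.0):
            raise ValueError("transition rows must be non-negative and sum to 1")
        R = self.covariances[0].shape[0]
        for c in self.covariances:
            if c.shape != (R, R) or not np.allclose(c, c.T):
                raise ValueError("covariances must be square and symmetric")
            if not np.allclose(np.diag(c), 1.0):
                raise ValueError("covariances must have unit diagonal")
            if np.linalg.eigvalsh(c)[0] < -1e-10:
                raise ValueError("covariance is not positive semi-definite")

    @property
    def n_states(self) -> int:
        return len(self.covariances)

    @property
    def n_regions(self) -> int:
        return self.covariances[0].shape[0]

    @property
    def dwell_mean_tr(self) -> float:
        """Mean dwell time implied by the self-transition probabilities."""
        stay = np.diag(self.transition)
        return float(np.mean(1.0 / np.maximum(1.0 - stay, 1e-12)))


def two_state_pair_model(
    corr_low: float, corr_high: float, switch_prob: float
) -> StateModel:
    """Two regions whose correlation toggles between two levels.

    ``switch_prob`` is the per-TR probability of leaving the current state
    (symmetric), so the mean dwell time is ``1 / switch_prob`` TR.
    """
    if not (0 <= switch_prob <= 1):
        raise ValueError("switch_prob must be in [0, 1]")
    covs = [
        np.array([[1.0, c], [c, 1.0]]) for c in (corr_low, corr_high)
    ]
    p = switch_prob
    return StateModel(covariances=covs, transition=np.array([[1 - p, p], [p, 1 - p]]))


def erlang_pair_model(
    corr_low: float, corr_high: float, switch_prob: float, shape: int = 8
) -> StateModel:
    """Two correlation levels with Erlang-distributed dwell times.

    Each level is realized as ``shape`` chained Markov sub-states sharing
    the level's covariance, traversed cyclically with advance probability
    ``shape * switch_prob``; the dwell time per level is then
    Erlang(shape) with mean ``1 / switch_prob`` TR and coefficient of
    variation ``1/sqrt(shape)``.  Compared with the plain two-state chain
    (``shape = 1``) this regularizes the number of state alternations a
    short scan realizes, which keeps the between-subject variance of the
    temporal-variability statistic commensurate with the planted effects.
    """
    if shape < 1:
        raise ValueError("shape must be >= 1")
    q = shape * switch_prob
    if not (0 <= q <= 1):
        raise ValueError(f"shape * switch_prob = {q} must be in [0, 1]")
    n = 2 * shape
    covs = [
        np.array([[1.0, c], [c, 1.0]])
        for c in [corr_low] * shape + [corr_high] * shape
    ]
    trans = np.zeros((n, n))
    for i in range(n):
        trans[i, i] = 1.0 - q
        trans[i, (i + 1) % n] = q
    return StateModel(covariances=covs, transition=trans)


def sample_state_sequence(
    model: StateModel, T: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Sample a hidden-state path of length T; the initial state is uniform."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    n = model.n_states
    states = np.empty(T, dtype=np.intp)
    cum = np.cumsum(model.transition, axis=1)
    states[0] = rng.integers(n)
    u = rng.random(T - 1)
    for t in range(1, T):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t - 1], side="right")
    return states


def _draw_state_gaussian(
    model: StateModel, states: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean Gaussian draws whose covariance follows the active state."""
    T = states.shape[0]
    R = model.n_regions
    z = rng.standard_normal((T, R))
    x = np.empty((T, R))
    for s, cov in enumerate(model.covariances):
        idx = states == s
        if not np.any(idx):
            continue
        # sqrtm via eigen-decomposition tolerates semidefinite states
        w, V = np.linalg.eigh(cov)
        L = V * np.sqrt(np.maximum(w, 0.0))
        x[idx] = z[idx] @ L.T
    return x


def generate_roi_bold(
    model: StateModel,
    states: np.ndarray,
    noise_sd: float,
    tr_seconds: float,
    seed: int | np.random.Generator,
) -> RoiTimeSeries:
    """BOLD-like multi-region series driven by a hidden-state path.

    At each TR a multivariate Gaussian sample is drawn under the active
    state's correlation matrix; white noise of ``noise_sd`` is added; the
    result is band-pass filtered (0.01-0.08 Hz) so its spectrum resembles
    filtered resting-state BOLD, and columns are standardized to unit
    variance.
    """
    states = np.asarray(states)
    if states.ndim != 1:
        raise ValueError("states must be a vector")
    if states.min() < 0 or states.max() >= model.n_states:
        raise ValueError("state index out of range")
    rng = np.random.default_rng(seed)
    x = _draw_state_gaussian(model, states, rng)
    x = x + noise_sd * rng.standard_normal(x.shape)
    x = bandpass(x, tr_seconds)
    x = x / x.std(axis=0, keepdims=True)
    labels = [f"roi{j:02d}" for j in range(model.n_regions)]
    return RoiTimeSeries(values=x, labels=labels, tr_seconds=tr_seconds)


@dataclass
class CohortDesign:
    """Study-design parameters of a synthetic longitudinal cohort.

    Defaults mirror the targeted acquisition: TR = 2 s scans of 255 volumes
    with the first five discarded before analysis, two patient groups of 20,
    a baseline-only healthy reference group, and a multiplicative reduction
    ``effect_delta`` of the state-switching rate on responsive pairs for
    treated subjects at t2.
    """

    n_per_group: int = 20
    n_hc: int = 12
    T: int = 255
    discard_volumes: int = 5
    tr_seconds: float = 2.0
    n_regions: int = 12
    effect_delta: float = 0.3
    responsive_pairs: list[tuple[int, int]] = field(
        default_factory=lambda: [(0, 1), (2, 3), (4, 5)]
    )
    #: per-block (corr_low, corr_high) levels; block k couples regions 2k, 2k+1.
    #: Responsive blocks swing between anticorrelated and strongly correlated
    #: states (large excursions of the windowed correlation); the remaining
    #: blocks hold high mean correlation with small swings, so mean FC and
    #: variability decouple negatively across pairs.
    block_corrs: list[tuple[float, float]] = field(
        default_factory=lambda: [
            (-0.80, 0.90),
            (-0.80, 0.85),
            (-0.75, 0.90),
            (0.70, 0.80),
            (0.55, 0.65),
            (0.35, 0.45),
        ]
    )
    base_switch_prob: float = 0.012
    dwell_shape: int = 8
    rate_sigma: float = 0.35
    noise_sd: float = 0.2
    clinical_link_slope: float = 0.34
    clinical_link_noise_sd: float = 0.03
    qc_fail_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.effect_delta <= 1):
            raise ValueError("effect_delta must be in (0, 1]")
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        if self.n_regions % 2 or self.n_regions < 2:
            raise ValueError("n_regions must be a positive even number (2-region blocks)")
        n_blocks = self.n_regions // 2
        if len(self.block_corrs) != n_blocks:
            raise ValueError(f"need {n_blocks} block_corrs entries")
        for i, j in self.responsive_pairs:
            if i >= self.n_regions or j >= self.n_regions:
                raise ValueError(f"responsive pair ({i}, {j}) exceeds region count")
            if j != i + 1 or i % 2:
                raise ValueError(
                    f"responsive pair ({i}, {j}) is not a generator block pair "
                    "(regions 2k, 2k+1); effects can only be planted on blocks"
                )
        if self.T - self.discard_volumes < 10:
            raise ValueError("too few volumes after discarding")


@dataclass
class SyntheticCohort:
    """A generated cohort: series, clinical table, motion, and ground truth."""

    roi_series: dict[tuple[str, str], RoiTimeSeries]
    cohort: pd.DataFrame
    motion: dict[tuple[str, str], np.ndarray]
    ground_truth: dict
    design: CohortDesign

    def patients(self) -> list[str]:
        df = self.cohort
        return sorted(df.loc[df["group"] != "HC", "subject_id"].unique())


def _block_series(
    design: CohortDesign,
    switch_probs: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Raw (unfiltered) region series from per-block two-state chains."""
    T = design.T
    n_blocks = design.n_regions // 2
    x = np.empty((T, design.n_regions))
    for b in range(n_blocks):
        c_low, c_high = design.block_corrs[b]
        p = min(float(switch_probs[b]), 0.99 / design.dwell_shape)
        model = erlang_pair_model(c_low, c_high, p, shape=design.dwell_shape)
        states = sample_state_sequence(model, T, rng)
        x[:, 2 * b : 2 * b + 2] = _draw_state_gaussian(model, states, rng)
    x += design.noise_sd * rng.standard_normal(x.shape)
    return x


def _preprocess(design: CohortDesign, raw: np.ndarray) -> RoiTimeSeries:
    kept = raw[design.discard_volumes :]
    filt = bandpass(kept, design.tr_seconds)
    filt = filt / filt.std(axis=0, keepdims=True)
    labels = [f"roi{j:02d}" for j in range(design.n_regions)]
    return RoiTimeSeries(values=filt, labels=labels, tr_seconds=design.tr_seconds)


def _motion_trace(
    T: int, rng: np.random.Generator, fail: bool
) -> np.ndarray:
    """Smooth random-walk motion trace; a planted failure spikes one axis."""
    steps = np.hstack(
        [
            rng.normal(0.0, 0.02, size=(T, 3)),  # translations, mm
            rng.normal(0.0, 2e-4, size=(T, 3)),  # rotations, rad
        ]
    )
    walk = np.cumsum(steps, axis=0)
    walk[:, :3] *= 0.8 / max(np.abs(walk[:, :3]).max(), 1e-12)
    walk[:, 3:] *= 0.008 / max(np.abs(walk[:, 3:]).max(), 1e-12)
    if fail:
        walk[T // 2 :, 0] += 4.0  # abrupt 4 mm shift fails the 3 mm criterion
    return walk


def _clip_round(value: np.ndarray | float, subscale: str) -> np.ndarray:
    lo, hi = PANSS_BOUNDS[subscale]
    return np.clip(np.round(value), lo, hi)


def generate_cohort(design: CohortDesign) -> SyntheticCohort:
    """Generate a full longitudinal cohort under ``design``.

    Treated (TSZ) subjects at t2 switch states at ``base rate x
    effect_delta`` on the responsive blocks; everything else uses the
    subject's base rate.  Each subject's base rate carries a lognormal
    multiplier, so baseline variability differs across subjects and the
    realized variability drop — and through it the planted negative-symptom
    remission ratio — is predictable from baseline features.
    """
    root = np.random.SeedSequence(design.seed)
    n_blocks = design.n_regions // 2
    responsive_blocks = [i // 2 for i, _ in design.responsive_pairs]
    scheme = WindowScheme(50, 1)
    if scheme.length_tr > design.T - design.discard_volumes:
        scheme = WindowScheme(max(2, (design.T - design.discard_volumes) // 3), 1)

    records: list[dict] = []
    roi_series: dict[tuple[str, str], RoiTimeSeries] = {}
    motion: dict[tuple[str, str], np.ndarray] = {}
    per_subject_truth: dict[str, dict] = {}

    groups = (
        [("TSZ", i) for i in range(design.n_per_group)]
        + [("DSZ", i) for i in range(design.n_per_group)]
        + [("HC", i) for i in range(design.n_hc)]
    )
    seeds = root.spawn(len(groups))
    for (group, i), subseed in zip(groups, seeds):
        rng = np.random.default_rng(subseed)
        sid = f"{group.lower()}{i:03d}"
        age = float(np.clip(rng.normal(46.0, 10.0), 18, 70))
        sex = "M" if rng.random() < 0.75 else "F"
        education = float(np.clip(rng.normal(11.0, 3.0), 0, 22))
        base = {
            "subject_id": sid,
            "group": group,
            "age_years": round(age, 1),
            "sex": sex,
            "education_years": round(education, 1),
        }
        rate_mult = float(rng.lognormal(0.0, design.rate_sigma))
        base_probs = np.full(n_blocks, design.base_switch_prob * rate_mult)
        qc_fail = rng.random() < design.qc_fail_fraction and group != "HC"

        if group == "HC":
            raw = _block_series(design, base_probs, rng)
            roi_series[(sid, "t1")] = _preprocess(design, raw)
            motion[(sid, "t1")] = _motion_trace(design.T, rng, fail=False)
            records.append(
                {
                    **base,
                    "timepoint": "t1",
                    "illness_duration_months": np.nan,
                    "cpz_equiv_mg_per_day": np.nan,
                    "panss_positive": np.nan,
                    "panss_negative": np.nan,
                    "panss_general": np.nan,
                    "panss_total": np.nan,
                }
            )
            continue

        illness = float(np.clip(rng.normal(18.0, 8.5), 1, 60))
        cpz = float(np.clip(rng.normal(300.0, 110.0), 50, 800))
        t2_probs = base_probs.copy()
        # Responsiveness scales with the subject's baseline switching level:
        # subjects with abnormally high switching normalize more (smaller
        # per-subject delta), so baseline variability predicts response.
        subject_delta = float(design.effect_delta ** (rate_mult**3))
        planted_drop = 1.0 - subject_delta
        if group == "TSZ":
            for b in responsive_blocks:
                t2_probs[b] *= subject_delta

        raw_t1 = _block_series(design, base_probs, rng)
        raw_t2 = _block_series(design, t2_probs, rng)
        series_t1 = _preprocess(design, raw_t1)
        series_t2 = _preprocess(design, raw_t2)
        roi_series[(sid, "t1")] = series_t1
        roi_series[(sid, "t2")] = series_t2
        motion[(sid, "t1")] = _motion_trace(design.T, rng, fail=qc_fail)
        motion[(sid, "t2")] = _motion_trace(design.T, rng, fail=False)

        var_t1 = roi_variability_matrix(series_t1, scheme)
        var_t2 = roi_variability_matrix(series_t2, scheme)
        drops = [
            (var_t1.values[i, j] - var_t2.values[i, j]) / var_t1.values[i, j]
            for i, j in design.responsive_pairs
        ]
        realized_drop = float(np.mean(drops))

        # baseline PANSS drawn around typical chronic-schizophrenia levels
        pos_t1 = _clip_round(rng.normal(11.7, 4.2), "positive")
        neg_t1 = _clip_round(rng.normal(22.7, 7.3), "negative")
        gen_t1 = _clip_round(rng.normal(29.7, 6.2), "general")
        if group == "TSZ":
            rr_neg = design.clinical_link_slope * planted_drop + rng.normal(
                0.0, design.clinical_link_noise_sd
            )
            rr_pos, rr_gen = (
                rng.normal(0.15, 0.10),
                rng.normal(0.15, 0.10),
            )
        else:
            rr_neg = rng.normal(0.07, 0.10)
            rr_pos, rr_gen = rng.normal(0.12, 0.10), rng.normal(0.07, 0.10)
        pos_t2 = _clip_round(pos_t1 * (1.0 - rr_pos), "positive")
        neg_t2 = _clip_round(neg_t1 * (1.0 - rr_neg), "negative")
        gen_t2 = _clip_round(gen_t1 * (1.0 - rr_gen), "general")

        for tp, (p, n, g) in {
            "t1": (pos_t1, neg_t1, gen_t1),
            "t2": (pos_t2, neg_t2, gen_t2),
        }.items():
            records.append(
                {
                    **base,
                    "timepoint": tp,
                    "illness_duration_months": round(illness, 1),
                    "cpz_equiv_mg_per_day": round(cpz, 1),
                    "panss_positive": float(p),
                    "panss_negative": float(n),
                    "panss_general": float(g),
                    "panss_total": float(p + n + g),
                }
            )
        per_subject_truth[sid] = {
            "rate_multiplier": rate_mult,
            "subject_delta": subject_delta,
            "planted_rel_drop": planted_drop,
            "switch_prob_t1": base_probs.tolist(),
            "switch_prob_t2": t2_probs.tolist(),
            "realized_rel_drop": realized_drop,
            "rr_negative_planted": float(rr_neg),
            "qc_fail_planted": bool(qc_fail),
        }

    cohort = pd.DataFrame.from_records(records)[COHORT_COLUMNS]
    labels = [f"roi{j:02d}" for j in range(design.n_regions)]
    ground_truth = {
        "responsive_pairs": [list(p) for p in design.responsive_pairs],
        "responsive_pair_labels": [
            [labels[i], labels[j]] for i, j in design.responsive_pairs
        ],
        "effect_delta": design.effect_delta,
        "per_subject": per_subject_truth,
    }
    return SyntheticCohort(
        roi_series=roi_series,
        cohort=cohort,
        motion=motion,
        ground_truth=ground_truth,
        design=design,
    )
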