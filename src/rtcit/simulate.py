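"""Synthetic cohort generator for the Go/No-go RT-CIT paradigm.

Generates, per participant: latent traits (primary/secondary psychopathy,
impulsivity, response-inhibition capacity), trial-level reaction times
under an ex-Gaussian model, item-level LSRP and BIS-11 responses with
configurable internal consistency, and post-test subjective ratings.

Calibration philosophy
----------------------
The generator is calibrated so that the *scored* quantities downstream
(scale totals, their correlations and reliabilities, the per-participant
RT-CIT effect distribution) reproduce the study-level summaries the
analysis assumes.  Latent trait correlations are therefore disattenuated
targets (target / sqrt(alpha_i * alpha_j)), and item loadings are
corrected for the information lost when a continuous latent response is
cut into a 4-point Likert category.

Under the default configuration the per-participant probe slowing
(``probe_shift_ms``) is drawn independently of every latent trait: the
null-consistent regime in which the concealed-information effect carries
no association with secondary psychopathy, impulsivity or inhibition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import DesignSpec

__all__ = [
    "ScaleDefinition", "TraitModelConfig", "ParticipantTraits",
    "LSRP_PRIMARY", "LSRP_SECONDARY", "BIS11", "disattenuate",
    "default_latent_correlation", "sample_traits", "generate_schedule",
    "generate_rts", "generate_item_responses", "generate_ratings",
    "simulate_cohort",
]

_LATENTS = ("primary", "secondary", "impulsivity", "inhibition")


@dataclass(frozen=True)
class ScaleDefinition:
    """One self-report scale: item count, latent source and targets.

    ``alpha`` is the Cronbach's-alpha target for the generated item
    matrix; ``item_mean`` the target mean response on the 1-4 Likert
    scale (scale mean / item count).
    """

    name: str
    n_items: int
    latent: str  # which latent trait the items load on
    alpha: float
    item_mean: float = 2.5
    n_categories: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError(f"reliability target must be in (0, 1], got {self.alpha}")
        if self.n_items < 2:
            raise ValueError("a scale needs at least 2 items")
        if self.latent not in _LATENTS:
            raise ValueError(f"unknown latent trait {self.latent!r}")


# Default scale structure: LSRP primary 16 items, secondary 10, BIS-11 30,
# with the study's observed reliabilities and scale means as targets.
LSRP_PRIMARY = ScaleDefinition("lsrp_primary", 16, "primary", 0.80, 28.34 / 16)
LSRP_SECONDARY = ScaleDefinition("lsrp_secondary", 10, "secondary", 0.63, 19.03 / 10)
BIS11 = ScaleDefinition("bis", 30, "impulsivity", 0.84, 63.03 / 30)


def disattenuate(target_r: float, alpha_x: float, alpha_y: float) -> float:
    """Latent correlation needed so two noisy scales correlate at ``target_r``.

    Classical-test-theory attenuation: observed r = latent r * sqrt(ax * ay).
    """
    latent = target_r / math.sqrt(alpha_x * alpha_y)
    if abs(latent) > 1:
        raise ValueError(
            f"target correlation {target_r} unreachable at reliabilities "
            f"{alpha_x}, {alpha_y}")
    return latent


def default_latent_correlation() -> np.ndarray:
    """Latent 4x4 correlation over (primary, secondary, impulsivity, inhibition).

    Off-diagonals are the scored-scale correlation targets disattenuated
    by the scale reliabilities; inhibition capacity correlates negatively
    with everything (more capacity, fewer commission errors).
    """
    a_p, a_s, a_b = LSRP_PRIMARY.alpha, LSRP_SECONDARY.alpha, BIS11.alpha
    m = np.eye(4)
    pairs = {
        (0, 1): disattenuate(0.300, a_p, a_s),
        (0, 2): disattenuate(0.185, a_p, a_b),
        (1, 2): disattenuate(0.516, a_s, a_b),
        (0, 3): -0.115 / math.sqrt(a_p),
        (1, 3): -0.079 / math.sqrt(a_s),
        (2, 3): -0.115 / math.sqrt(a_b),
    }
    for (i, j), r in pairs.items():
        m[i, j] = m[j, i] = r
    return m


@dataclass
class TraitModelConfig:
    """Population model behind the synthetic cohort.

    RT quantities are in milliseconds.  ``probe_shift_mean_ms`` /
    ``probe_shift_sd_ms`` set the between-subject distribution of the
    RT-CIT effect; ``base_rt_mean_ms`` / ``base_rt_between_sd_ms`` the
    distribution of per-participant mean irrelevant RT;
    ``within_sd_irrelevant_ms`` the trial-to-trial SD of a single
    participant's irrelevant RTs, split into a Gaussian and an
    exponential (``exgauss_tau_ms``) component.
    """

    latent_correlation: np.ndarray = field(default_factory=default_latent_correlation)
    scales: tuple[ScaleDefinition, ...] = (LSRP_PRIMARY, LSRP_SECONDARY, BIS11)
    probe_shift_mean_ms: float = 54.91
    probe_shift_sd_ms: float = 32.43
    target_shift_mean_ms: float = 40.0
    target_shift_sd_ms: float = 15.0
    base_rt_mean_ms: float = 477.47
    base_rt_between_sd_ms: float = 33.28
    within_sd_irrelevant_ms: float = 100.0
    exgauss_tau_ms: float = 60.0
    commission_mean: float = 0.312       # mean no-go false-press probability
    commission_between_sd: float = 0.141
    error_prob_go: float = 0.05          # wrong-button probability on go trials
    # probe_shift correlation with the latent traits; 0 = the null regime
    probe_shift_trait_corr: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    # post-test rating (mean, sd) pairs
    rating_probe_significance: tuple[float, float] = (8.58, 1.21)
    rating_irrelevant_significance: tuple[float, float] = (1.94, 1.10)
    rating_motivation: tuple[float, float] = (7.71, 2.2)
    rating_impulsivity: tuple[float, float] = (6.22, 2.16)

    def __post_init__(self) -> None:
        m = np.asarray(self.latent_correlation, dtype=float)
        if m.shape != (4, 4) or not np.allclose(m, m.T):
            raise ValueError("latent_correlation must be a symmetric 4x4 matrix")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("latent_correlation must have unit diagonal")
        if np.linalg.eigvalsh(m).min() < -1e-10:
            raise ValueError("latent_correlation must be positive semi-definite")
        self.latent_correlation = m
        if self.within_sd_irrelevant_ms <= self.exgauss_tau_ms:
            raise ValueError("within-subject SD must exceed the exponential tau")
        for p in (self.commission_mean, self.error_prob_go):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def exgauss_sigma_ms(self) -> float:
        """Gaussian SD so that total within-subject SD hits the target."""
        return math.sqrt(self.within_sd_irrelevant_ms ** 2 - self.exgauss_tau_ms ** 2)


@dataclass
class ParticipantTraits:
    """Latent quantities of one synthetic participant."""

    participant_id: str
    z_primary: float
    z_secondary: float
    z_impulsivity: float
    z_inhibition: float
    base_mu_ms: float
    base_sigma_ms: float
    base_tau_ms: float
    probe_shift_ms: float
    target_shift_ms: float
    commission_prob: float
    error_prob_go: float

    def __post_init__(self) -> None:
        if not (0 <= self.commission_prob <= 1 and 0 <= self.error_prob_go <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.base_sigma_ms <= 0 or self.base_tau_ms < 0:
            raise ValueError("base_sigma_ms > 0 and base_tau_ms >= 0 required")


def sample_traits(n: int, config: TraitModelConfig | None = None,
                  rng: np.random.Generator | None = None) -> list[ParticipantTraits]:
    """Draw ``n`` participants from the population model.

    Latent traits come from a multivariate standard normal with the
    configured correlation matrix; the probe shift is normal with the
    configured mean/SD and, by default, independent of every latent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or TraitModelConfig()
    rng = rng if rng is not None else np.random.default_rng()

    z = rng.multivariate_normal(np.zeros(4), config.latent_correlation,
                                size=n, method="cholesky")
    # optional correlation between the probe shift and the latents, via a
    # linear combination plus independent residual
    w = np.asarray(config.probe_shift_trait_corr, dtype=float)
    lin = z @ np.linalg.solve(config.latent_correlation, w)
    explained = float(w @ np.linalg.solve(config.latent_correlation, w))
    if explained > 1:
        raise ValueError("probe_shift_trait_corr implies variance > 1")
    shift_z = lin + math.sqrt(1 - explained) * rng.standard_normal(n)
    probe_shift = config.probe_shift_mean_ms + config.probe_shift_sd_ms * shift_z

    tau = config.exgauss_tau_ms
    base_mu = rng.normal(config.base_rt_mean_ms - tau,
                         config.base_rt_between_sd_ms, size=n)
    target_shift = rng.normal(config.target_shift_mean_ms,
                              config.target_shift_sd_ms, size=n)
    commission = np.clip(
        config.commission_mean - config.commission_between_sd * z[:, 3],
        0.02, 0.98)

    width = max(3, len(str(n)))
    return [
        ParticipantTraits(
            participant_id=f"P{i + 1:0{width}d}",
            z_primary=float(z[i, 0]), z_secondary=float(z[i, 1]),
            z_impulsivity=float(z[i, 2]), z_inhibition=float(z[i, 3]),
            base_mu_ms=float(base_mu[i]),
            base_sigma_ms=config.exgauss_sigma_ms,
            base_tau_ms=tau,
            probe_shift_ms=float(probe_shift[i]),
            target_shift_ms=float(target_shift[i]),
            commission_prob=float(commission[i]),
            error_prob_go=config.error_prob_go,
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# trial schedule


def generate_schedule(design: DesignSpec,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Randomized session schedule: no item on two consecutive trials.

    Each block is a random permutation of ``reps_per_block`` copies of
    every item; adjacent repeats (including across block boundaries, the
    session being continuous) are repaired by re-drawing a swap partner
    for the offending position, falling back to a full reshuffle.

    Returns trial stubs: participant-free rows with ``block``,
    ``trial_index``, ``item_id``, ``stim_type`` and ``isi_ms``.
    """
    labels = design.item_labels()
    if len(labels) == 1 and design.reps_per_block > 1:
        raise ValueError("cannot avoid adjacent repeats with a single item")

    pool = np.repeat(np.arange(len(labels)), design.reps_per_block)
    blocks: list[np.ndarray] = []
    prev_last = -1
    for _ in range(design.n_blocks):
        blocks.append(_block_order(pool, prev_last, rng))
        prev_last = blocks[-1][-1]

    order = np.concatenate(blocks)
    item_ids = np.array([lab for lab, _ in labels])
    stim_types = np.array([st for _, st in labels])
    n = design.total_trials
    return pd.DataFrame({
        "block": np.repeat(np.arange(1, design.n_blocks + 1),
                           design.trials_per_block),
        "trial_index": np.arange(1, n + 1),
        "item_id": item_ids[order],
        "stim_type": stim_types[order],
        "isi_ms": rng.choice(np.asarray(design.isi_options_ms), size=n),
    })


def _block_order(pool: np.ndarray, prev_last: int,
                 rng: np.random.Generator, max_reshuffles: int = 200) -> np.ndarray:
    """One block's item order with no adjacent repeats (incl. vs prev_last)."""
    for _ in range(max_reshuffles):
        seq = rng.permutation(pool)
        if _repair(seq, prev_last, rng):
            return seq
    raise RuntimeError("could not satisfy the no-repeat constraint; "
                       "design too dense")


def _repair(seq: np.ndarray, prev_last: int, rng: np.random.Generator,
            max_tries: int = 400) -> bool:
    """Swap away adjacent repeats in-place; True on success."""
    n = len(seq)
    for _ in range(max_tries):
        bad = np.flatnonzero(seq[1:] == seq[:-1]) + 1
        if prev_last >= 0 and seq[0] == prev_last:
            bad = np.concatenate(([0], bad))
        if bad.size == 0:
            return True
        i = int(bad[0])
        j = int(rng.integers(n))
        if _swap_ok(seq, i, j, prev_last):
            seq[i], seq[j] = seq[j], seq[i]
    return False


def _swap_ok(seq: np.ndarray, i: int, j: int, prev_last: int) -> bool:
    """Would swapping positions i and j leave both neighborhoods repeat-free?"""
    if i == j or seq[i] == seq[j]:
        return False
    n = len(seq)

    def neighbors(k: int, incoming: int) -> bool:
        left = seq[k - 1] if k > 0 else prev_last
        if k - 1 == i:
            left = seq[j]
        elif k - 1 == j:
            left = seq[i]
        right = seq[k + 1] if k + 1 < n else -1
        if k + 1 == i:
            right = seq[j]
        elif k + 1 == j:
            right = seq[i]
        return incoming != left and incoming != right

    return neighbors(i, int(seq[j])) and neighbors(j, int(seq[i]))


# ---------------------------------------------------------------------------
# reaction times


def generate_rts(schedule: pd.DataFrame, traits: ParticipantTraits,
                 design: DesignSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Fill a schedule with simulated responses and latencies.

    Go-trial RTs are ex-Gaussian(mu, sigma, tau) with an additive
    per-participant probe or target shift; a draw beyond the stimulus
    duration is an omission (no press recorded).  Wrong-button presses
    occur with ``error_prob_go``; no-go presses (commission errors) with
    ``commission_prob``, their latency drawn from the go distribution.
    """
    n = len(schedule)
    stim = schedule["stim_type"].to_numpy()
    shift = np.zeros(n)
    shift[stim == "probe"] = traits.probe_shift_ms
    shift[stim == "target"] = traits.target_shift_ms

    rt = (traits.base_mu_ms + shift
          + traits.base_sigma_ms * rng.standard_normal(n)
          + rng.exponential(traits.base_tau_ms, size=n))
    rt = np.maximum(rt, 1.0)  # physical floor; essentially never binds

    is_go = stim != "nogo"
    pressed = np.where(is_go, rt <= design.stim_duration_ms, False)
    commit = rng.random(n) < traits.commission_prob
    pressed |= (~is_go) & commit & (rt <= design.stim_duration_ms)

    wrong = rng.random(n) < traits.error_prob_go
    correct_button = np.where(stim == "target", "familiar", "unfamiliar")
    other_button = np.where(stim == "target", "unfamiliar", "familiar")
    response = np.full(n, "none", dtype=object)
    response[pressed & is_go & ~wrong] = correct_button[pressed & is_go & ~wrong]
    response[pressed & is_go & wrong] = other_button[pressed & is_go & wrong]
    # commission presses follow the habitual go response
    response[pressed & ~is_go] = "unfamiliar"

    out = schedule.copy()
    out.insert(0, "participant_id", traits.participant_id)
    out["rt_ms"] = np.where(pressed, np.round(rt, 1), np.nan)
    out["response"] = response
    out["correct"] = np.where(
        is_go, (response == correct_button) & pressed, ~pressed)
    return out


# ---------------------------------------------------------------------------
# questionnaire items

def _thresholds(scale: ScaleDefinition) -> np.ndarray:
    """Category cutpoints on the latent response scale.

    Unit-spaced cutpoints shifted so that the expected categorized
    response matches the scale's target item mean.
    """
    base = np.arange(1, scale.n_categories) - scale.n_categories / 2  # e.g. -1,0,1

    def mean_minus_target(c: float) -> float:
        return 1 + float(np.sum(stats.norm.sf(base + c))) - scale.item_mean

    c = optimize.brentq(mean_minus_target, -6, 6)
    return base + c


def _categorization_attenuation(cuts: np.ndarray) -> float:
    """Squared correlation between a N(0,1) variable and its categorized form.

    Pairwise correlations between categorized items shrink by roughly
    this factor relative to their latent counterparts; item loadings are
    inflated by 1/a^2 to compensate.
    """
    cov = float(np.sum(stats.norm.pdf(cuts)))
    p = np.diff(np.concatenate(([0.0], stats.norm.cdf(cuts), [1.0])))
    vals = np.arange(len(p))
    var = float(p @ vals ** 2 - (p @ vals) ** 2)
    return cov ** 2 / var


def generate_item_responses(traits: list[ParticipantTraits],
                            scale: ScaleDefinition,
                            rng: np.random.Generator) -> pd.DataFrame:
    """Graded 1..4 item responses with the scale's target reliability.

    Each item is loading * latent + noise, cut at the scale's thresholds.
    The common inter-item correlation is set from the Spearman-Brown
    inversion of the alpha target and corrected for categorization loss.
    """
    k, alpha = scale.n_items, scale.alpha
    rho_cat = alpha / (k - alpha * (k - 1))  # target observed inter-item r
    cuts = _thresholds(scale)
    rho_latent = rho_cat / _categorization_attenuation(cuts)
    if rho_latent >= 1:
        raise ValueError(
            f"reliability {alpha} with {k} items is unreachable after "
            "categorization loss")
    lam = math.sqrt(rho_latent)

    z = np.array([getattr(t, f"z_{scale.latent}") for t in traits])
    latent = lam * z[:, None] + math.sqrt(1 - lam ** 2) * rng.standard_normal(
        (len(traits), k))
    responses = 1 + np.searchsorted(cuts, latent.ravel()).reshape(latent.shape)
    cols = [f"{scale.name}_item_{i + 1:02d}" for i in range(k)]
    df = pd.DataFrame(responses.astype(int), columns=cols)
    df.insert(0, "participant_id", [t.participant_id for t in traits])
    return df


def _latent_rating_mean(target: float, sd: float, hi: int) -> float:
    """Latent normal mean whose rounded-and-clipped draws average ``target``.

    Near the scale ends, rounding + clipping pulls the observed mean
    toward the middle; the latent mean is shifted to compensate so the
    configured value is the mean a study would actually report.
    """
    ks = np.arange(1, hi + 1)

    def observed_mean(m: float) -> float:
        upper = stats.norm.cdf((ks + 0.5 - m) / sd)
        upper[-1] = 1.0
        lower = np.concatenate(([0.0], upper[:-1]))
        return float(ks @ (upper - lower))

    if not 1 < target < hi:
        raise ValueError(f"rating mean target must lie inside (1, {hi})")
    return optimize.brentq(lambda m: observed_mean(m) - target,
                           target - 6 * sd, target + 6 * sd)


def generate_ratings(traits: list[ParticipantTraits],
                     rng: np.random.Generator,
                     config: TraitModelConfig | None = None) -> pd.DataFrame:
    """Post-test ratings: probe/irrelevant significance (1-9), motivation
    and felt impulsivity (1-10); normal draws rounded and clipped.

    Configured means are targets for the OBSERVED (rounded, clipped)
    ratings; the underlying normal mean is calibrated accordingly.
    """
    config = config or TraitModelConfig()
    n = len(traits)

    def draw(mean_sd: tuple[float, float], hi: int) -> np.ndarray:
        m, s = mean_sd
        latent_m = _latent_rating_mean(m, s, hi)
        return np.clip(np.round(rng.normal(latent_m, s, size=n)), 1, hi).astype(int)

    return pd.DataFrame({
        "participant_id": [t.participant_id for t in traits],
        "rating_probe_significance": draw(config.rating_probe_significance, 9),
        "rating_irrelevant_significance": draw(
            config.rating_irrelevant_significance, 9),
        "rating_motivation": draw(config.rating_motivation, 10),
        "rating_impulsivity": draw(config.rating_impulsivity, 10),
    })


# ---------------------------------------------------------------------------
# one-call cohort


def simulate_cohort(n: int, design: DesignSpec | None = None,
                    config: TraitModelConfig | None = None,
                    seed: int | np.random.SeedSequence | None = None,
                    ) -> dict[str, pd.DataFrame]:
    """Generate a full synthetic study: trials + questionnaire + ratings.

    One master seed spawns independent substreams per stage (traits,
    schedules/RTs, items, ratings) so that re-running a single stage does
    not perturb another's draws.

    Returns ``{"trials": ..., "questionnaire": ..., "traits": ...}``; the
    questionnaire table carries one row per participant with LSRP and
    BIS-11 items plus the rating columns.
    """
    design = design or DesignSpec()
    config = config or TraitModelConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    s_traits, s_trials, s_items, s_ratings = ss.spawn(4)

    traits = sample_traits(n, config, np.random.default_rng(s_traits))

    trial_rng = np.random.default_rng(s_trials)
    trial_frames = []
    for t in traits:
        sched = generate_schedule(design, trial_rng)
        trial_frames.append(generate_rts(sched, t, design, trial_rng))
    trials = pd.concat(trial_frames, ignore_index=True)

    item_rng = np.random.default_rng(s_items)
    q = None
    offsets = {"lsrp_primary": 0, "lsrp_secondary": LSRP_PRIMARY.n_items}
    for scale in config.scales:
        part = generate_item_responses(traits, scale, item_rng)
        if scale.name in offsets:
            # LSRP is published as one 26-item questionnaire; the default
            # key maps items 1-16 to primary and 17-26 to secondary
            off = offsets[scale.name]
            part = part.rename(columns={
                f"{scale.name}_item_{i + 1:02d}": f"lsrp_item_{off + i + 1:02d}"
                for i in range(scale.n_items)})
        q = part if q is None else q.merge(part, on="participant_id")
    ratings = generate_ratings(traits, np.random.default_rng(s_ratings), config)
    q = q.merge(ratings, on="participant_id")

    trait_df = pd.DataFrame([vars(t) for t in traits])
    return {"trials": trials, "questionnaire": q, "traits": trait_df}
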