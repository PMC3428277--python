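"""Synthetic cohorts standing in for the access-restricted repositories.

Three generators:

* :func:`generate_cohort` — a planted-signal case/control cohort shaped
  like the training repository (891 cases vs 75 controls, age quartiles
  matched by a truncated log-normal).  A small informative item subset
  carries the entire class separation; all other items share one
  background distribution in both classes, so they are label-independent
  up to the accept/reject step that makes every case satisfy — and every
  control fail — the diagnostic algorithm.
* :func:`resample_controls` — new control sheets drawn item-by-item,
  uniformly with replacement, from the observed control answer pool, so
  each item's marginal matches the observed controls.
* :func:`simulate_near_cutoff_controls` — constrained sheets whose three
  domain totals land uniformly in a margin just below their cutoffs:
  behaviourally borderline subjects that still carry a non-spectrum
  classification.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Sequence
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .instrument import (
    AUTISM,
    NON_SPECTRUM,
    AnswerSheet,
    ConfigError,
    Cutoffs,
    DEFAULT_DOMAIN_MAPPING,
    DomainMapping,
    N_ITEMS,
    PUBLISHED_SUBSET,
    ValidationError,
    recode_array,
)

#: Raw exception codes injected into generated sheets.
_EXCEPTION_CODES = np.array([7, 8, 9])


@dataclass(frozen=True)
class AgeQuartiles:
    """Target age quartiles in years; sampling uses a log-normal fitted to
    the median and IQR, truncated to the configured age window."""

    q1: float
    median: float
    q3: float

    def __post_init__(self) -> None:
        if not (0 < self.q1 < self.median < self.q3):
            raise ConfigError("age quartiles must be increasing and positive")


@dataclass(frozen=True)
class CohortConfig:
    """Study-shaped cohort: sizes, planted signal, ages, exception codes.

    The informative items default to the seven-item published subset; a
    case scores 2 on an informative item with probability ``p_high_case``
    (0 otherwise) and a control with ``p_high_control``.  Background items
    share ``background`` = P(score 0,1,2) in both classes.  Raw sheets get
    severity code 3 in place of a 2 at ``severity3_rate`` and an exception
    code (7/8/9) at ``exception_rate``; the first ``n_forced_exclusion``
    item ids (outside the domains and the planted set) receive exception
    codes at ``forced_exception_rate`` > 0.5 so item exclusion is exercised
    end to end.
    """

    n_cases: int = 891
    n_controls: int = 75
    informative_items: tuple[int, ...] = tuple(sorted(PUBLISHED_SUBSET))
    p_high_case: float = 0.9
    p_high_control: float = 0.05
    background: tuple[float, float, float] = (0.55, 0.30, 0.15)
    exception_rate: float = 0.02
    severity3_rate: float = 0.10
    n_forced_exclusion: int = 3
    forced_exception_rate: float = 0.70
    case_ages: AgeQuartiles = AgeQuartiles(6.44, 8.06, 10.84)
    control_ages: AgeQuartiles = AgeQuartiles(6.38, 9.24, 11.88)
    age_min_years: float = 5.0
    age_max_years: float = 17.0
    verbal_fraction: float = 0.8
    mapping: DomainMapping = DEFAULT_DOMAIN_MAPPING
    cutoffs: Cutoffs = field(default_factory=Cutoffs)
    max_retries: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_high_case", "p_high_control", "exception_rate",
                     "severity3_rate", "verbal_fraction", "forced_exception_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0,1]")
        if min(self.n_cases, self.n_controls) < 0:
            raise ConfigError("cohort sizes must be >= 0")
        if abs(sum(self.background) - 1.0) > 1e-9 or min(self.background) < 0:
            raise ConfigError("background must be a probability vector over {0,1,2}")
        if self.forced_exception_rate <= 0.5 and self.n_forced_exclusion > 0:
            raise ConfigError("forced_exception_rate must exceed 0.5")
        if self.age_min_years >= self.age_max_years:
            raise ConfigError("age window is empty")

    @property
    def forced_exclusion_items(self) -> tuple[int, ...]:
        """Item ids given majority exception codes: the lowest ids outside
        the domain mapping and the planted set."""
        reserved = set(self.mapping.all_items) | set(self.informative_items)
        free = [i for i in range(1, N_ITEMS + 1) if i not in reserved]
        if self.n_forced_exclusion > len(free):
            raise ConfigError("not enough free items to force-exclude")
        return tuple(free[: self.n_forced_exclusion])


def _lognormal_ages_months(
    rng: np.random.Generator,
    n: int,
    quartiles: AgeQuartiles,
    min_years: float,
    max_years: float,
) -> np.ndarray:
    """Truncated log-normal ages, in integer months."""
    mu = np.log(quartiles.median)
    # 0.6745 = standard normal upper quartile.
    sigma = np.log(quartiles.q3 / quartiles.q1) / (2 * 0.6745)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, sigma, size=max(n - filled, 16))
        ok = draw[(draw >= min_years) & (draw < max_years)]
        take = ok[: n - filled]
        out[filled : filled + take.size] = take
        filled += take.size
    months = np.floor(out * 12).astype(np.int32)
    return np.clip(months, int(np.ceil(min_years * 12)), int(max_years * 12) - 1)


def _draw_raw_rows(
    rng: np.random.Generator, cfg: CohortConfig, n: int, is_case: bool
) -> np.ndarray:
    """Raw answer rows (n × 93) for one class, before constraint checking."""
    p_high = cfg.p_high_case if is_case else cfg.p_high_control
    info = np.array(cfg.informative_items) - 1
    forced = np.array(cfg.forced_exclusion_items, dtype=int) - 1 if cfg.n_forced_exclusion else np.empty(0, dtype=int)
    scores = rng.choice(3, size=(n, N_ITEMS), p=cfg.background).astype(np.int16)
    scores[:, info] = np.where(rng.random((n, info.size)) < p_high, 2, 0)
    raw = scores.copy()
    # Severity: some definite-abnormality answers recorded at extreme severity.
    sev = (scores == 2) & (rng.random((n, N_ITEMS)) < cfg.severity3_rate)
    raw[sev] = 3
    # Exception codes, recoded to 0 downstream.
    exc = rng.random((n, N_ITEMS)) < cfg.exception_rate
    if forced.size:
        exc[:, forced] = rng.random((n, forced.size)) < cfg.forced_exception_rate
    raw[exc] = rng.choice(_EXCEPTION_CODES, size=int(exc.sum()))
    return raw


def _criterion_mask(
    raw: np.ndarray, verbal: np.ndarray, cfg: CohortConfig
) -> np.ndarray:
    """True where a raw row meets the diagnostic algorithm (after recoding)."""
    rec = recode_array(raw)
    soc = rec[:, np.array(cfg.mapping.social) - 1].sum(axis=1)
    com = rec[:, np.array(cfg.mapping.communication) - 1].sum(axis=1)
    rrb = rec[:, np.array(cfg.mapping.rrb) - 1].sum(axis=1)
    cut = cfg.cutoffs
    comm_cut = np.where(verbal, cut.comm_cut_verbal, cut.comm_cut_nonverbal)
    return (soc >= cut.social_cut) & (com >= comm_cut) & (rrb >= cut.rrb_cut)


def _generate_class(
    rng: np.random.Generator, cfg: CohortConfig, n: int, is_case: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw rows, verbal flags and ages for one class, resampling each sheet
    until it satisfies (cases) or fails (controls) the diagnostic rule."""
    verbal = rng.random(n) < cfg.verbal_fraction
    quartiles = cfg.case_ages if is_case else cfg.control_ages
    ages = _lognormal_ages_months(rng, n, quartiles, cfg.age_min_years, cfg.age_max_years)
    raw = _draw_raw_rows(rng, cfg, n, is_case)
    for attempt in range(cfg.max_retries + 1):
        meets = _criterion_mask(raw, verbal, cfg)
        bad = ~meets if is_case else meets
        if not bad.any():
            return raw, verbal, ages
        if attempt == cfg.max_retries:
            break
        idx = np.flatnonzero(bad)
        raw[idx] = _draw_raw_rows(rng, cfg, idx.size, is_case)
    idx = np.flatnonzero(bad)
    # Report which domain blocks the remaining sheets.
    rec = recode_array(raw[idx])
    cut = cfg.cutoffs
    fails = {
        "social": int((rec[:, np.array(cfg.mapping.social) - 1].sum(axis=1) < cut.social_cut).sum()),
        "communication": int(
            (
                rec[:, np.array(cfg.mapping.communication) - 1].sum(axis=1)
                < np.where(verbal[idx], cut.comm_cut_verbal, cut.comm_cut_nonverbal)
            ).sum()
        ),
        "rrb": int((rec[:, np.array(cfg.mapping.rrb) - 1].sum(axis=1) < cut.rrb_cut).sum()),
    }
    side = "satisfy" if is_case else "fail"
    raise ConfigError(
        f"could not {side} the diagnostic criterion for {idx.size} sheets after "
        f"{cfg.max_retries} retries; sub-cutoff counts per domain: {fails}"
    )


def generate_cohort(cfg: CohortConfig = CohortConfig()) -> list[AnswerSheet]:
    """Planted-signal case/control cohort; every case satisfies and every
    control fails the diagnostic algorithm under the configured mapping."""
    rng = np.random.default_rng(cfg.seed)
    sheets: list[AnswerSheet] = []
    for is_case, n, prefix, diagnosis in (
        (True, cfg.n_cases, "case", AUTISM),
        (False, cfg.n_controls, "ctrl", NON_SPECTRUM),
    ):
        if n == 0:
            continue
        raw, verbal, ages = _generate_class(rng, cfg, n, is_case)
        for i in range(n):
            sheets.append(
                AnswerSheet(
                    subject_id=f"{prefix}_{i + 1:04d}",
                    age_months=int(ages[i]),
                    verbal=bool(verbal[i]),
                    diagnosis=diagnosis,
                    answers={j + 1: int(raw[i, j]) for j in range(N_ITEMS)},
                )
            )
    return sheets


# ---------------------------------------------------------------------------
# Observed-pool resampling
# ---------------------------------------------------------------------------


@dataclass
class ControlPool:
    """Per-item multisets of raw answers observed on non-spectrum sheets,
    plus the source rows for whole-row resampling."""

    item_answers: dict[int, Counter]
    rows: list[dict[int, int]]
    ages_months: list[int]
    verbal: list[bool]

    def __post_init__(self) -> None:
        empty = [i for i, c in self.item_answers.items() if not c]
        if empty:
            raise ValidationError(f"empty answer multiset for items {empty}")


def build_control_pool(sheets: Sequence[AnswerSheet]) -> ControlPool:
    """Pool the raw answers of the non-spectrum sheets, item by item."""
    controls = [sh for sh in sheets if sh.diagnosis == NON_SPECTRUM]
    if not controls:
        raise ValidationError("no non-spectrum sheets to pool")
    item_ids = sorted(controls[0].answers)
    item_answers = {
        i: Counter(sh.answers[i] for sh in controls if i in sh.answers) for i in item_ids
    }
    return ControlPool(
        item_answers=item_answers,
        rows=[dict(sh.answers) for sh in controls],
        ages_months=[sh.age_months for sh in controls],
        verbal=[sh.verbal for sh in controls],
    )


def resample_controls(
    pool: ControlPool, n: int = 1000, seed: int = 0, mode: str = "item"
) -> list[AnswerSheet]:
    """Simulated controls drawn from the observed pool.

    ``mode="item"`` (default) samples every item independently and
    uniformly with replacement from that item's multiset, so the output
    marginals match the pool item by item.  ``mode="row"`` copies whole
    observed rows (a sensitivity-analysis variant preserving inter-item
    correlation).  Demographics are resampled from the pool's subjects.
    """
    if mode not in ("item", "row"):
        raise ConfigError(f"unknown resampling mode {mode!r}")
    if n <= 0:
        return []
    rng = np.random.default_rng(seed)
    item_ids = sorted(pool.item_answers)
    value_arrays = {
        i: np.array(sorted(pool.item_answers[i].elements())) for i in item_ids
    }
    sheets = []
    for k in range(n):
        if mode == "item":
            answers = {
                i: int(value_arrays[i][rng.integers(value_arrays[i].size)])
                for i in item_ids
            }
        else:
            answers = dict(pool.rows[rng.integers(len(pool.rows))])
        demo = rng.integers(len(pool.ages_months))
        sheets.append(
            AnswerSheet(
                subject_id=f"resamp_{k + 1:04d}",
                age_months=pool.ages_months[demo],
                verbal=pool.verbal[demo],
                diagnosis=NON_SPECTRUM,
                answers=answers,
            )
        )
    return sheets


# ---------------------------------------------------------------------------
# Near-cutoff constrained controls
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NearCutoffConfig:
    """Borderline non-spectrum sheets: each domain total is drawn uniformly
    from [max(0, cutoff−δ), cutoff−1], so every sheet fails all three
    cutoffs while staying close to them.  Sheets are verbal by default so
    the communication range is a single interval; items outside the three
    domains come from the background distribution."""

    n: int = 1000
    cutoffs: Cutoffs = field(default_factory=Cutoffs)
    delta: int = 3
    mapping: DomainMapping = DEFAULT_DOMAIN_MAPPING
    background: tuple[float, float, float] = (0.80, 0.15, 0.05)
    verbal: bool = True
    age_min_years: float = 5.0
    age_max_years: float = 17.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta < 1:
            raise ConfigError("delta must be >= 1")
        if self.n < 0:
            raise ConfigError("n must be >= 0")
        if abs(sum(self.background) - 1.0) > 1e-9 or min(self.background) < 0:
            raise ConfigError("background must be a probability vector over {0,1,2}")
        comm_cut = self.cutoffs.communication_cut(self.verbal)
        for name, cut, items in (
            ("social", self.cutoffs.social_cut, self.mapping.social),
            ("communication", comm_cut, self.mapping.communication),
            ("rrb", self.cutoffs.rrb_cut, self.mapping.rrb),
        ):
            if cut - 1 > 2 * len(items):
                raise ConfigError(
                    f"{name}: max target {cut - 1} exceeds capacity 2×{len(items)}"
                )


@lru_cache(maxsize=None)
def _n_compositions(m: int, total: int) -> int:
    """Number of score vectors in {0,1,2}^m summing to ``total``."""
    if total < 0 or total > 2 * m:
        return 0
    if m == 0:
        return 1 if total == 0 else 0
    return sum(_n_compositions(m - 1, total - s) for s in (0, 1, 2))


def allocate_domain_total(
    total: int, m: int, rng: np.random.Generator, per_item_max: int = 2
) -> list[int]:
    """Uniformly random scores in {0..per_item_max}^m summing to ``total``.

    Exact uniformity over all compositions via dynamic-programming counts
    and an integer inverse-CDF walk.
    """
    if per_item_max != 2:
        raise NotImplementedError("scores are on the 0-2 scale")
    if not (0 <= total <= per_item_max * m):
        raise ValidationError(f"total {total} infeasible for {m} items")
    scores = []
    remaining = total
    for k in range(m, 0, -1):
        u = int(rng.integers(_n_compositions(k, remaining)))
        for s in (0, 1, 2):
            c = _n_compositions(k - 1, remaining - s)
            if u < c:
                scores.append(s)
                remaining -= s
                break
            u -= c
    assert remaining == 0
    return scores


def simulate_near_cutoff_controls(cfg: NearCutoffConfig = NearCutoffConfig()) -> list[AnswerSheet]:
    """Constrained sheets failing every domain cutoff from just below."""
    rng = np.random.default_rng(cfg.seed)
    domain_items = {
        "social": cfg.mapping.social,
        "communication": cfg.mapping.communication,
        "rrb": cfg.mapping.rrb,
    }
    domain_cut = {
        "social": cfg.cutoffs.social_cut,
        "communication": cfg.cutoffs.communication_cut(cfg.verbal),
        "rrb": cfg.cutoffs.rrb_cut,
    }
    other_items = [
        i for i in range(1, N_ITEMS + 1) if i not in set(cfg.mapping.all_items)
    ]
    sheets = []
    for k in range(cfg.n):
        answers: dict[int, int] = {}
        for name, items in domain_items.items():
            cut = domain_cut[name]
            low = max(0, cut - cfg.delta)
            target = int(rng.integers(low, cut))  # uniform on [low, cut-1]
            for item_id, s in zip(items, allocate_domain_total(target, len(items), rng)):
                answers[item_id] = s
        bg = rng.choice(3, size=len(other_items), p=cfg.background)
        answers.update({i: int(v) for i, v in zip(other_items, bg)})
        age_months = int(
            rng.integers(int(cfg.age_min_years * 12), int(cfg.age_max_years * 12))
        )
        sheet = AnswerSheet(
            subject_id=f"nearcut_{k + 1:04d}",
            age_months=age_months,
            verbal=cfg.verbal,
            diagnosis=NON_SPECTRUM,
            answers=answers,
        )
        sheets.append(sheet)
    return sheets
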