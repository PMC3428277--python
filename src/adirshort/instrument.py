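"""ADI-R instrument data model: items, answer sheets, recoding and the
diagnostic algorithm.

The Autism Diagnostic Interview-Revised (ADI-R) is a 93-item caregiver
interview.  Raw item codes are 0 (behaviour absent), 1 (present but below
threshold), 2 (definite abnormality), 3 (extreme severity) plus the
exception codes 7 (abnormality of a different type), 8 (not applicable) and
9 (not known / not asked).  For scoring, 3 collapses to 2 and every
exception code collapses to 0, giving an ordinal 0-2 scale per item.

The instrument's published diagnostic algorithm sums recoded scores within
three behavioural domains — reciprocal social interaction, communication
and restricted/repetitive behaviours (RRB) — and classifies a subject as
autism when every domain total meets its cutoff: 10 for social, 8
(verbal) / 7 (nonverbal) for communication, 3 for RRB.

The licensed item→domain assignment is not distributed with this package;
the default mapping shipped here is a synthetic stand-in (see
:data:`DEFAULT_DOMAIN_MAPPING`) used by the simulators and clearly labelled
non-canonical.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Codes and labels
# ---------------------------------------------------------------------------

RAW_CODES = frozenset({0, 1, 2, 3, 7, 8, 9})
EXCEPTION_CODES = frozenset({7, 8, 9})

AUTISM = "autism"
NON_SPECTRUM = "non_spectrum"
UNKNOWN = "unknown"
DIAGNOSES = frozenset({AUTISM, NON_SPECTRUM, UNKNOWN})

#: Signed class labels used throughout: negative = autism so that the
#: alternating-decision-tree score sign convention (negative score = autism)
#: holds by construction.
LABEL_AUTISM = -1
LABEL_NON_SPECTRUM = +1

N_ITEMS = 93

#: The seven-item subset reported to preserve the full instrument's
#: classification (item number → abbreviation).
PUBLISHED_SUBSET = {
    29: "compsl5",
    35: "conver5",
    48: "play5",
    49: "peerpl5",
    50: "gaze5",
    64: "grplay5",
    86: "ageabn",
}


class ValidationError(ValueError):
    """Raised when input data violate the instrument's contracts."""


class ConfigError(ValueError):
    """Raised when a configuration value is structurally invalid."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ItemDefinition:
    """One questionnaire item.

    ``domain`` is one of ``social`` / ``communication`` / ``rrb`` for items
    entering the diagnostic algorithm, or ``none`` otherwise.
    """

    item_id: int
    abbreviation: str
    domain: str = "none"
    description: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.item_id <= N_ITEMS):
            raise ValidationError(f"item_id {self.item_id} outside 1..{N_ITEMS}")
        if self.domain not in {"social", "communication", "rrb", "none"}:
            raise ValidationError(f"unknown domain {self.domain!r}")


@dataclass
class AnswerSheet:
    """One subject's raw ADI-R answers plus demographics and diagnosis."""

    subject_id: str
    age_months: int
    verbal: bool
    diagnosis: str
    answers: dict[int, int]

    def validate(self, retained: Iterable[int] | None = None) -> None:
        if self.age_months < 0:
            raise ValidationError(
                f"subject {self.subject_id}: negative age {self.age_months}"
            )
        if self.diagnosis not in DIAGNOSES:
            raise ValidationError(
                f"subject {self.subject_id}: unknown diagnosis {self.diagnosis!r}"
            )
        for item_id, raw in self.answers.items():
            if raw not in RAW_CODES:
                raise ValidationError(
                    f"subject {self.subject_id}, item {item_id}: "
                    f"raw code {raw!r} not in {sorted(RAW_CODES)}"
                )
        if retained is not None:
            missing = [i for i in retained if i not in self.answers]
            if missing:
                raise ValidationError(
                    f"subject {self.subject_id}: missing items {missing}"
                )

    @property
    def age_years(self) -> float:
        return self.age_months / 12.0


@dataclass
class RecodedMatrix:
    """Subjects × retained items on the recoded 0-2 scale, with labels.

    ``labels`` are −1 (autism) / +1 (non-spectrum).  Ages and verbal status
    are carried along so downstream evaluation can subgroup by age without
    going back to the raw sheets.
    """

    subject_ids: list[str]
    item_ids: list[int]
    scores: np.ndarray  # shape (n_subjects, n_items), int8 in {0,1,2}
    labels: np.ndarray  # shape (n_subjects,), values in {-1,+1}
    ages_months: np.ndarray | None = None
    verbal: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int8)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.scores.shape != (len(self.subject_ids), len(self.item_ids)):
            raise ValidationError("scores shape does not match ids")
        if self.labels.shape[0] != len(self.subject_ids):
            raise ValidationError("label count does not match subject count")
        if self.scores.size and not np.isin(self.scores, (0, 1, 2)).all():
            raise ValidationError("recoded scores must lie in {0,1,2}")
        if self.labels.size and not np.isin(self.labels, (-1, 1)).all():
            raise ValidationError("labels must lie in {-1,+1}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def column(self, item_id: int) -> np.ndarray:
        return self.scores[:, self.item_ids.index(item_id)]

    def row_mapping(self, i: int) -> dict[int, int]:
        """Item → recoded score mapping for subject ``i``."""
        return dict(zip(self.item_ids, self.scores[i].tolist()))

    def subset(self, mask: np.ndarray) -> "RecodedMatrix":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return RecodedMatrix(
            subject_ids=[self.subject_ids[i] for i in idx],
            item_ids=list(self.item_ids),
            scores=self.scores[idx],
            labels=self.labels[idx],
            ages_months=None if self.ages_months is None else self.ages_months[idx],
            verbal=None if self.verbal is None else self.verbal[idx],
        )


@dataclass(frozen=True)
class DomainScores:
    social: int
    communication: int
    rrb: int

    def __post_init__(self) -> None:
        if min(self.social, self.communication, self.rrb) < 0:
            raise ValidationError("domain totals must be non-negative")


@dataclass(frozen=True)
class Cutoffs:
    """Diagnostic algorithm cutoffs (published defaults)."""

    social_cut: int = 10
    comm_cut_verbal: int = 8
    comm_cut_nonverbal: int = 7
    rrb_cut: int = 3

    def __post_init__(self) -> None:
        if min(
            self.social_cut,
            self.comm_cut_verbal,
            self.comm_cut_nonverbal,
            self.rrb_cut,
        ) < 1:
            raise ConfigError("cutoffs must be strictly positive")

    def communication_cut(self, verbal: bool) -> int:
        return self.comm_cut_verbal if verbal else self.comm_cut_nonverbal


@dataclass(frozen=True)
class DomainMapping:
    """Item → domain assignment for the diagnostic algorithm."""

    social: tuple[int, ...]
    communication: tuple[int, ...]
    rrb: tuple[int, ...]

    def __post_init__(self) -> None:
        all_items = self.social + self.communication + self.rrb
        if len(set(all_items)) != len(all_items):
            raise ConfigError("an item may belong to at most one domain")

    @property
    def all_items(self) -> tuple[int, ...]:
        return self.social + self.communication + self.rrb

    def domain_of(self, item_id: int) -> str:
        if item_id in self.social:
            return "social"
        if item_id in self.communication:
            return "communication"
        if item_id in self.rrb:
            return "rrb"
        return "none"


#: Synthetic stand-in for the licensed item→domain assignment, used by the
#: simulators; NOT the instrument's canonical algorithm item list.  Sizes
#: are 15 social, 13 communication, 8 RRB items, and the seven published
#: classifier items are spread over the three domains.
DEFAULT_DOMAIN_MAPPING = DomainMapping(
    social=(49, 50, 64, 51, 52, 53, 54, 55, 56, 57, 58, 59, 60, 61, 62),
    communication=(29, 35, 30, 31, 32, 33, 34, 36, 37, 38, 39, 40, 41),
    rrb=(48, 86, 67, 68, 69, 70, 71, 72),
)


def default_items(mapping: DomainMapping = DEFAULT_DOMAIN_MAPPING) -> list[ItemDefinition]:
    """Build the default 93-item instrument definition.

    Published abbreviations are used for the seven reported classifier items;
    the remaining items carry generic ``q<nn>`` abbreviations.
    """
    items = []
    for i in range(1, N_ITEMS + 1):
        abbrev = PUBLISHED_SUBSET.get(i, f"q{i:02d}")
        items.append(ItemDefinition(item_id=i, abbreviation=abbrev, domain=mapping.domain_of(i)))
    return items


@dataclass
class Instrument:
    """An instrument version: item definitions, domain mapping, cutoffs."""

    items: list[ItemDefinition] = field(default_factory=default_items)
    mapping: DomainMapping = DEFAULT_DOMAIN_MAPPING
    cutoffs: Cutoffs = field(default_factory=Cutoffs)
    #: Items excluded regardless of data (special isolated skills, optional
    #: hand-written answers); configurable per instrument version.
    force_exclude: tuple[int, ...] = ()
    version: str = "synthetic-default-1"

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate item_id in instrument")
        abbrevs = [it.abbreviation for it in self.items]
        if len(set(abbrevs)) != len(abbrevs):
            raise ValidationError("duplicate abbreviation in instrument")

    @property
    def item_ids(self) -> list[int]:
        return [it.item_id for it in self.items]

    def abbreviation(self, item_id: int) -> str:
        return self._by_id()[item_id].abbreviation

    def item_by_abbreviation(self, abbrev: str) -> ItemDefinition:
        for it in self.items:
            if it.abbreviation == abbrev:
                return it
        raise KeyError(abbrev)

    def _by_id(self) -> dict[int, ItemDefinition]:
        return {it.item_id: it for it in self.items}


# ---------------------------------------------------------------------------
# Recoding
# ---------------------------------------------------------------------------


def recode_answer(raw: int, *, item_id: int | None = None, subject_id: str | None = None) -> int:
    """Map a raw item code onto the 0-2 scoring scale.

    0/1/2 map to themselves, severity code 3 collapses to 2, and the
    exception codes 7/8/9 collapse to 0.
    """
    if raw in (0, 1, 2):
        return raw
    if raw == 3:
        return 2
    if raw in EXCEPTION_CODES:
        return 0
    raise ValidationError(
        f"raw code {raw!r} not in {sorted(RAW_CODES)}"
        + (f" (item {item_id}" if item_id is not None else "")
        + (f", subject {subject_id})" if subject_id is not None else (")" if item_id is not None else ""))
    )


# Vectorised recode lookup: index by raw code value (0..9).
_RECODE_LUT = np.full(10, -1, dtype=np.int8)
for _raw in RAW_CODES:
    _RECODE_LUT[_raw] = recode_answer(_raw)


def recode_array(raw: np.ndarray) -> np.ndarray:
    """Elementwise :func:`recode_answer` for integer arrays."""
    raw = np.asarray(raw)
    if raw.size and (raw.min() < 0 or raw.max() > 9 or (_RECODE_LUT[raw] < 0).any()):
        bad = np.unique(raw[~np.isin(raw, list(RAW_CODES))])
        raise ValidationError(f"raw codes {bad.tolist()} not in {sorted(RAW_CODES)}")
    return _RECODE_LUT[raw]


def recode_cohort(sheets: Sequence[AnswerSheet], retained: Sequence[int]) -> RecodedMatrix:
    """Recode a cohort into the subjects × retained-items score matrix.

    Sheets with an unknown diagnosis are excluded with a logged warning.
    Labels encode autism = −1 and non-spectrum = +1.
    """
    retained = list(retained)
    if not retained:
        raise ValidationError("retained item list is empty")
    kept: list[AnswerSheet] = []
    for sh in sheets:
        if sh.diagnosis == UNKNOWN:
            logger.warning("excluding subject %s: unknown diagnosis", sh.subject_id)
            continue
        sh.validate(retained)
        kept.append(sh)
    if not kept:
        raise ValidationError("no sheets with a known diagnosis")
    raw = np.array([[sh.answers[i] for i in retained] for sh in kept], dtype=np.int16)
    scores = recode_array(raw)
    labels = np.array(
        [LABEL_AUTISM if sh.diagnosis == AUTISM else LABEL_NON_SPECTRUM for sh in kept],
        dtype=np.int8,
    )
    return RecodedMatrix(
        subject_ids=[sh.subject_id for sh in kept],
        item_ids=retained,
        scores=scores,
        labels=labels,
        ages_months=np.array([sh.age_months for sh in kept], dtype=np.int32),
        verbal=np.array([sh.verbal for sh in kept], dtype=bool),
    )


# ---------------------------------------------------------------------------
# Item exclusion
# ---------------------------------------------------------------------------


def identify_excluded_items(
    sheets: Sequence[AnswerSheet],
    exception_fraction_threshold: float = 0.5,
    force_exclude: Iterable[int] = (),
) -> list[int]:
    """Items to drop before learning.

    An item is excluded when the fraction of its raw answers that are
    exception codes (7/8/9) exceeds the threshold — a *strict* majority at
    the default 0.5 — plus any item in the configured force-exclude list
    (special isolated skills / optional hand-written items).
    """
    if not (0 < exception_fraction_threshold <= 1):
        raise ConfigError("exception_fraction_threshold must lie in (0, 1]")
    counts: dict[int, list[int]] = {}
    for sh in sheets:
        for item_id, raw in sh.answers.items():
            n_exc, n_tot = counts.setdefault(item_id, [0, 0])
            counts[item_id][1] = n_tot + 1
            if raw in EXCEPTION_CODES:
                counts[item_id][0] = n_exc + 1
    excluded = {
        item_id
        for item_id, (n_exc, n_tot) in counts.items()
        if n_tot and n_exc / n_tot > exception_fraction_threshold
    }
    excluded.update(force_exclude)
    return sorted(excluded)


# ---------------------------------------------------------------------------
# Domain scoring and the diagnostic algorithm
# ---------------------------------------------------------------------------


def domain_scores(recoded: Mapping[int, int], mapping: DomainMapping) -> DomainScores:
    """Sum recoded scores within the three behavioural domains.

    ``recoded`` must cover every item used by the algorithm mapping.
    """
    missing = [i for i in mapping.all_items if i not in recoded]
    if missing:
        raise ValidationError(f"recoded scores missing algorithm items {missing}")
    return DomainScores(
        social=sum(recoded[i] for i in mapping.social),
        communication=sum(recoded[i] for i in mapping.communication),
        rrb=sum(recoded[i] for i in mapping.rrb),
    )


def sheet_domain_scores(sheet: AnswerSheet, mapping: DomainMapping) -> DomainScores:
    """Recode a raw sheet and compute its domain totals."""
    recoded = {
        i: recode_answer(sheet.answers[i], item_id=i, subject_id=sheet.subject_id)
        for i in mapping.all_items
        if i in sheet.answers
    }
    return domain_scores(recoded, mapping)


def adir_algorithm_classify(
    ds: DomainScores, verbal: bool, cutoffs: Cutoffs = Cutoffs()
) -> str:
    """Published diagnostic rule: autism iff every domain total meets its
    cutoff (meets-or-exceeds; the communication cutoff depends on verbal
    status)."""
    meets = (
        ds.social >= cutoffs.social_cut
        and ds.communication >= cutoffs.communication_cut(verbal)
        and ds.rrb >= cutoffs.rrb_cut
    )
    return AUTISM if meets else NON_SPECTRUM


# ---------------------------------------------------------------------------
# Age filtering
# ---------------------------------------------------------------------------


def filter_by_age(
    sheets: Sequence[AnswerSheet],
    min_years: float | None = None,
    max_years: float | None = None,
) -> list[AnswerSheet]:
    """Retain sheets with min_years ≤ age < max_years (half-open).

    Either bound may be omitted; a max-only filter supports the under-5
    subgroup analysis.
    """
    out = []
    for sh in sheets:
        months = sh.age_months
        if min_years is not None and months < min_years * 12:
            continue
        if max_years is not None and months >= max_years * 12:
            continue
        out.append(sh)
    return out


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------


def write_answer_sheets(
    sheets: Sequence[AnswerSheet],
    path,
    instrument: Instrument,
    sep: str = ",",
) -> None:
    """Write sheets as delimited text: subject_id, age_months, verbal,
    diagnosis, then one bare-integer column per item named by abbreviation."""
    item_ids = instrument.item_ids
    cols = {
        "subject_id": [sh.subject_id for sh in sheets],
        "age_months": [sh.age_months for sh in sheets],
        "verbal": [int(sh.verbal) for sh in sheets],
        "diagnosis": [sh.diagnosis for sh in sheets],
    }
    for i in item_ids:
        cols[instrument.abbreviation(i)] = [sh.answers.get(i, 9) for sh in sheets]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


def read_answer_sheets(path, instrument: Instrument, sep: str = ",") -> list[AnswerSheet]:
    """Read the delimited answer-sheet format written by
    :func:`write_answer_sheets`.  Unknown codes must be written as 9."""
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str})
    required = {"subject_id", "age_months", "verbal", "diagnosis"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"answer-sheet file missing columns {sorted(missing)}")
    abbrev_to_id = {it.abbreviation: it.item_id for it in instrument.items}
    item_cols = [c for c in df.columns if c in abbrev_to_id]
    sheets = []
    for _, row in df.iterrows():
        answers = {abbrev_to_id[c]: int(row[c]) for c in item_cols}
        sh = AnswerSheet(
            subject_id=str(row["subject_id"]),
            age_months=int(row["age_months"]),
            verbal=bool(int(row["verbal"])),
            diagnosis=str(row["diagnosis"]),
            answers=answers,
        )
        sh.validate()
        sheets.append(sh)
    return sheets


def save_instrument(instrument: Instrument, path) -> None:
    """Persist an instrument definition (items, mapping, cutoffs) as YAML."""
    doc = {
        "version": instrument.version,
        "cutoffs": {
            "social_cut": instrument.cutoffs.social_cut,
            "comm_cut_verbal": instrument.cutoffs.comm_cut_verbal,
            "comm_cut_nonverbal": instrument.cutoffs.comm_cut_nonverbal,
            "rrb_cut": instrument.cutoffs.rrb_cut,
        },
        "mapping": {
            "social": list(instrument.mapping.social),
            "communication": list(instrument.mapping.communication),
            "rrb": list(instrument.mapping.rrb),
        },
        "force_exclude": list(instrument.force_exclude),
        "items": [
            {
                "item_id": it.item_id,
                "abbreviation": it.abbreviation,
                "domain": it.domain,
                "description": it.description,
            }
            for it in instrument.items
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_instrument(path) -> Instrument:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        mapping = DomainMapping(
            social=tuple(doc["mapping"]["social"]),
            communication=tuple(doc["mapping"]["communication"]),
            rrb=tuple(doc["mapping"]["rrb"]),
        )
        cutoffs = Cutoffs(**doc["cutoffs"])
        items = [ItemDefinition(**d) for d in doc["items"]]
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed instrument config: {exc}") from exc
    return Instrument(
        items=items,
        mapping=mapping,
        cutoffs=cutoffs,
        force_exclude=tuple(doc.get("force_exclude", ())),
        version=str(doc.get("version", "unversioned")),
    )
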