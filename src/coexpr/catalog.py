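"""Sample cataloguing: tissue/disease labels from free-text descriptions, plus quality filters.

Public RNA-seq repositories attach free-text tissue descriptions to each
sample rather than controlled vocabulary.  This module assigns tissue and
disease (cancer vs normal) labels by matching curated regular-expression
dictionaries against those descriptions, with negative patterns that veto
ambiguous matches (e.g. "cortex" identifies brain tissue *unless* "kidney"
also appears).  It then applies a three-stage quality filter: single-cell
samples are removed by description terms, samples with fewer than 5 million
aligned reads are dropped, and (tissue, disease) groups with fewer than 30
surviving samples are discarded entirely, since small strata yield unstable
co-expression estimates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import pandas as pd

from .errors import DictionaryError, ParameterError

logger = logging.getLogger(__name__)

#: sentinel strings used in TSV serialization
UNASSIGNED = "unassigned"
REASON_NONE = "none"
REASON_SCRNA = "scrna"
REASON_LOW_READS = "low_reads"
REASON_SMALL_GROUP = "small_group"

DEFAULT_MIN_READS = 5_000_000
DEFAULT_MIN_GROUP_SIZE = 30


@dataclass
class SampleRecord:
    """One sequencing sample with its metadata and filter verdicts.

    ``excluded`` is true iff ``exclusion_reason != "none"``; ``tissue_label``
    is ``None`` iff no dictionary term matched positively (or the match was
    ambiguous between two tissue labels).
    """

    sample_id: str
    tissue_description: str
    total_reads: int
    tissue_label: str | None = None
    disease_label: str = "normal"
    is_scrna: bool = False
    excluded: bool = False
    exclusion_reason: str = REASON_NONE

    def __post_init__(self) -> None:
        if self.total_reads < 0:
            raise ParameterError(
                f"sample {self.sample_id!r}: total_reads must be non-negative"
            )


def normalize_description(text: str) -> str:
    """Lowercase and collapse whitespace, preserving word boundaries."""
    return " ".join(str(text).lower().split())


class RegexDictionary:
    """A label -> {positive, negative} regex mapping, compiled at load time.

    A description carries label L iff at least one positive pattern of L
    matches and no negative pattern of L matches.  Patterns are tried against
    the whitespace-normalized description as a whole and against each
    individual token, so anchored terms like ``^pfc$`` act token-level while
    ``\\bstriatum\\b`` works on the full string.
    """

    def __init__(self, entries: Mapping[str, Mapping[str, Sequence[str]]]):
        self.entries: dict[str, tuple[list[re.Pattern], list[re.Pattern]]] = {}
        for label, spec in entries.items():
            if label in self.entries:
                raise DictionaryError(f"duplicate label {label!r}")
            pos = [self._compile(label, p) for p in spec.get("positive", [])]
            neg = [self._compile(label, p) for p in spec.get("negative", [])]
            self.entries[label] = (pos, neg)

    @staticmethod
    def _compile(label: str, pattern: str) -> re.Pattern:
        try:
            return re.compile(pattern)
        except re.error as exc:
            raise DictionaryError(
                f"label {label!r}: invalid regex {pattern!r}: {exc}"
            ) from exc

    @property
    def labels(self) -> list[str]:
        return list(self.entries)

    @staticmethod
    def _hits(pattern: re.Pattern, desc: str, tokens: Sequence[str]) -> bool:
        if pattern.search(desc):
            return True
        return any(pattern.search(tok) for tok in tokens)

    def match(self, description: str) -> list[str]:
        """All labels whose positive patterns match and negative ones do not."""
        desc = normalize_description(description)
        tokens = desc.split()
        out = []
        for label, (pos, neg) in self.entries.items():
            if not any(self._hits(p, desc, tokens) for p in pos):
                continue
            if any(self._hits(p, desc, tokens) for p in neg):
                continue
            out.append(label)
        return sorted(out)


def categorize_sample(description: str, tissue_dict: RegexDictionary) -> str | None:
    """Assign a tissue label, or None if nothing matched or the match is ambiguous.

    When two or more tissue labels both pass positive-and-not-negative
    matching the sample is deliberately left unassigned (and logged): an
    automated tool must not guess between conflicting curated terms.
    """
    labels = tissue_dict.match(description)
    if len(labels) == 1:
        return labels[0]
    if len(labels) > 1:
        logger.warning(
            "ambiguous tissue match %s for description %r; leaving unassigned",
            labels,
            description,
        )
    return None


def assign_disease(description: str, disease_dict: RegexDictionary) -> str:
    """Return "cancer" on a positive-minus-negative match, else "normal".

    Normal is the default: the disease dictionary identifies cancer evidence,
    and everything without such evidence is treated as non-cancer.
    """
    if disease_dict.labels != ["cancer"]:
        raise DictionaryError(
            f"disease dictionary must define exactly the 'cancer' label, "
            f"got {disease_dict.labels}"
        )
    return "cancer" if disease_dict.match(description) else "normal"


def flag_scrna(description: str, scrna_dict: RegexDictionary) -> bool:
    """True iff any single-cell term (e.g. "single cell", "scrna", "in-drop") matches."""
    return bool(scrna_dict.match(description))


def annotate_records(
    records: Iterable[SampleRecord],
    tissue_dict: RegexDictionary,
    disease_dict: RegexDictionary,
    scrna_dict: RegexDictionary,
) -> list[SampleRecord]:
    """Return copies of the records with tissue/disease labels and scRNA flags set."""
    out = []
    for rec in records:
        out.append(
            dataclasses.replace(
                rec,
                tissue_label=categorize_sample(rec.tissue_description, tissue_dict),
                disease_label=assign_disease(rec.tissue_description, disease_dict),
                is_scrna=flag_scrna(rec.tissue_description, scrna_dict),
            )
        )
    return out


def apply_filters(
    records: Sequence[SampleRecord],
    min_reads: int = DEFAULT_MIN_READS,
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
) -> list[SampleRecord]:
    """Apply the three-stage filter; returns new records with exclusion verdicts.

    Exclusion reasons are assigned in priority order scrna > low_reads >
    small_group, and group sizes are counted on (tissue, disease) pairs
    *after* the scrna/low-reads removals.  "Fewer than" is a strict ``<`` for
    both thresholds.  Samples without an assigned tissue belong to no group
    and are excluded as small_group.  The operation is idempotent.
    """
    if min_reads < 0 or min_group_size < 0:
        raise ParameterError("min_reads and min_group_size must be non-negative")
    out = []
    for rec in records:
        rec = dataclasses.replace(rec, excluded=False, exclusion_reason=REASON_NONE)
        if rec.is_scrna:
            rec.excluded, rec.exclusion_reason = True, REASON_SCRNA
        elif rec.total_reads < min_reads:
            rec.excluded, rec.exclusion_reason = True, REASON_LOW_READS
        out.append(rec)

    sizes: dict[tuple[str, str], int] = {}
    for rec in out:
        if not rec.excluded and rec.tissue_label is not None:
            key = (rec.tissue_label, rec.disease_label)
            sizes[key] = sizes.get(key, 0) + 1
    for rec in out:
        if rec.excluded:
            continue
        if (
            rec.tissue_label is None
            or sizes[(rec.tissue_label, rec.disease_label)] < min_group_size
        ):
            rec.excluded, rec.exclusion_reason = True, REASON_SMALL_GROUP
    return out


# ---------------------------------------------------------------------------
# external interfaces

METADATA_COLUMNS = ["sample_id", "tissue_description", "total_reads"]
CATALOG_COLUMNS = METADATA_COLUMNS + [
    "tissue_label",
    "disease_label",
    "excluded",
    "exclusion_reason",
]


def read_metadata_tsv(path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tissue_description": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"metadata TSV {path} lacks required columns {missing}")
    return [
        SampleRecord(
            sample_id=row.sample_id,
            tissue_description=row.tissue_description,
            total_reads=int(row.total_reads),
        )
        for row in df.itertuples()
    ]


def records_to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "tissue_description": r.tissue_description,
                "total_reads": r.total_reads,
                "tissue_label": r.tissue_label if r.tissue_label is not None else UNASSIGNED,
                "disease_label": r.disease_label,
                "excluded": r.excluded,
                "exclusion_reason": r.exclusion_reason,
            }
        )
    return pd.DataFrame(rows, columns=CATALOG_COLUMNS)


def write_catalog_tsv(records: Sequence[SampleRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tissue_description": str})
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"catalog TSV {path} lacks required columns {missing}")
    out = []
    for row in df.itertuples():
        tissue = None if row.tissue_label == UNASSIGNED else row.tissue_label
        out.append(
            SampleRecord(
                sample_id=row.sample_id,
                tissue_description=row.tissue_description,
                total_reads=int(row.total_reads),
                tissue_label=tissue,
                disease_label=row.disease_label,
                # scrna always outranks the other reasons, so the flag is
                # recoverable from the recorded verdict
                is_scrna=row.exclusion_reason == REASON_SCRNA,
                excluded=bool(row.excluded),
                exclusion_reason=row.exclusion_reason,
            )
        )
    return out


def load_dictionaries(path) -> tuple[RegexDictionary, RegexDictionary, RegexDictionary]:
    """Load the (tissues, disease, scrna) dictionaries from the JSON layout.

    Expected shape::

        {"tissues": {label: {"positive": [...], "negative": [...]}, ...},
         "disease": {"cancer": {...}},
         "scrna":   {"scrna": {"positive": [...]}}}

    For convenience the "scrna" section may also be a bare
    ``{"positive": [...]}`` mapping.
    """
    with open(path) as fh:
        raw = json.load(fh)
    for key in ("tissues", "disease", "scrna"):
        if key not in raw:
            raise DictionaryError(f"dictionary JSON {path} lacks section {key!r}")
    scrna = raw["scrna"]
    if "positive" in scrna and not isinstance(scrna["positive"], dict):
        scrna = {"scrna": scrna}
    return (
        RegexDictionary(raw["tissues"]),
        RegexDictionary(raw["disease"]),
        RegexDictionary(scrna),
    )
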