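"""Data model, I/O and aggregation for diallel crossing experiments.

A *cross record* is a single controlled pollination with its stage
outcomes: pollen-tube progression scored 0-4 at ~24 h post-pollination,
fruit set, fruit weight, seed counts/weights and germination. Records are
aggregated per directed female x male combination and classified on an
ordinal 1-8 crossability index (1 = fully fertile selfing/intraspecific
cross, 8 = pollen tubes arrested at the top of the stigma).
"""

from __future__ import annotations

import csv
import json
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: pollen-tube progression scale (score -> meaning)
POLLEN_SCALE = {
    0: "halted before stigma half",
    1: "halted at stigma end or style",
    2: "reached distal ovary",
    3: "reached proximal ovary",
    4: "fertilizing ovules",
}

FERTILITY_CLASSES = ("fertile", "male_sterile", "fully_sterile", "unknown")

#: crossability level (5-8, pre-zygotic arrest) implied by the modal
#: pollen score; lower scores mean earlier arrest and a more severe level.
_ARREST_LEVEL = {0: 8, 1: 7, 2: 6, 3: 5}

#: crossability level -> 0-4 pollen-progression scale
_CI_TO_POLLEN = {8: 0, 7: 1, 6: 2, 5: 3, 4: 4, 3: 4, 2: 4, 1: 4}


@dataclass(frozen=True)
class CrossRecord:
    """One pollination event with its stage outcomes.

    ``None`` encodes a missing observation throughout.
    """

    female_taxon: str
    male_taxon: str
    replicate_id: str = ""
    pollen_score: int | None = None
    ovules_fertilized: bool | None = None
    fruit_set: bool = False
    fruit_weight: float | None = None
    seed_count: int | None = None
    seed_weight: float | None = None
    seeds_sown: int = 0
    seeds_germinated: int = 0
    recorded_48h: bool = False

    @property
    def is_self(self) -> bool:
        return self.female_taxon == self.male_taxon

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any broken invariant."""
        if not self.female_taxon or not self.male_taxon:
            raise ValidationError("female_taxon and male_taxon are required")
        if self.pollen_score is not None and self.pollen_score not in POLLEN_SCALE:
            raise ValidationError(
                f"pollen_score must be in 0-4 or missing, got {self.pollen_score!r}"
            )
        if self.fruit_weight is not None and self.fruit_weight < 0:
            raise ValidationError(f"fruit_weight must be >= 0, got {self.fruit_weight}")
        if self.seed_count is not None and self.seed_count < 0:
            raise ValidationError(f"seed_count must be >= 0, got {self.seed_count}")
        if self.seed_weight is not None and self.seed_weight < 0:
            raise ValidationError(f"seed_weight must be >= 0, got {self.seed_weight}")
        if self.seeds_sown < 0 or self.seeds_germinated < 0:
            raise ValidationError("seed counts must be non-negative")
        if self.seeds_germinated > self.seeds_sown:
            raise ValidationError(
                f"seeds_germinated ({self.seeds_germinated}) exceeds "
                f"seeds_sown ({self.seeds_sown})"
            )
        if not self.fruit_set and (
            self.fruit_weight is not None or self.seed_count is not None
        ):
            raise ValidationError(
                "fruit_weight/seed_count must be missing when fruit_set is false"
            )


@dataclass
class CrossSummary:
    """Aggregate of all records for one directed female x male combination."""

    female_taxon: str
    male_taxon: str
    n_pollinations: int
    mean_pollen_score: float | None = None
    modal_pollen_score: int | None = None
    n_pollen_scored: int = 0
    any_ovules_fertilized: bool = False
    fruit_set_fraction: float = 0.0
    mean_fruit_weight: float | None = None
    mean_seed_count: float | None = None
    mean_seed_weight: float | None = None
    germination_rate: float | None = None
    total_seeds_sown: int = 0
    hybrid_fertility: str = "unknown"

    @property
    def is_self(self) -> bool:
        return self.female_taxon == self.male_taxon


@dataclass(frozen=True)
class CrossabilityIndex:
    """Ordinal 1-8 crossability level for one directed cross.

    ``level`` is ``None`` when the available summary fields are not
    sufficient to decide; ``reason`` then explains what was missing.
    ``fertilized_but_failed`` marks crosses whose pollen tubes fertilized
    ovules even though the assigned level is pre-zygotic (>= 5).
    """

    level: int | None
    fertilized_but_failed: bool = False
    reason: str = ""

    @property
    def undetermined(self) -> bool:
        return self.level is None


@dataclass
class TableSchema:
    """How to parse a cross-record table.

    ``aliases`` maps header names found in the file to canonical field
    names. ``lenient`` coerces soft invariant violations (seed fields
    present without fruit set) to missing instead of rejecting the row.
    """

    delimiter: str = "\t"
    na_token: str = "NA"
    aliases: Mapping[str, str] = field(default_factory=dict)
    lenient: bool = False
    allow_48h: bool = False


_FIELDS = {
    "female_taxon",
    "male_taxon",
    "replicate_id",
    "pollen_score",
    "ovules_fertilized",
    "fruit_set",
    "fruit_weight",
    "seed_count",
    "seed_weight",
    "seeds_sown",
    "seeds_germinated",
    "recorded_48h",
}

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n"}


def _parse_bool(text: str, row: int, fieldname: str) -> bool:
    low = text.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValidationError(f"row {row}: field {fieldname!r}: not a boolean: {text!r}")


def _parse_num(text: str, row: int, fieldname: str, kind=float):
    try:
        value = kind(text)
    except ValueError:
        raise ValidationError(
            f"row {row}: field {fieldname!r}: not a number: {text!r}"
        ) from None
    return value


def read_cross_records(
    path: str | Path, schema: TableSchema | None = None
) -> list[CrossRecord]:
    """Read and validate a delimited cross-record table.

    Every row is validated against the record invariants; a malformed row
    raises :class:`ValidationError` naming the row number and field. Under
    ``schema.lenient`` seed/fruit fields present on a no-fruit row are
    coerced to missing (and logged) instead of rejected.
    """
    schema = schema or TableSchema()
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    records: list[CrossRecord] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter=schema.delimiter)
        if reader.fieldnames is None:
            raise ValidationError(f"empty file: {path}")
        columns = {}
        for name in reader.fieldnames:
            canonical = schema.aliases.get(name, name)
            if canonical in _FIELDS:
                columns[name] = canonical
        if "female_taxon" not in columns.values() or "male_taxon" not in columns.values():
            raise ValidationError(
                f"{path}: header must provide female_taxon and male_taxon "
                f"(found: {reader.fieldnames})"
            )
        for i, raw in enumerate(reader, start=2):  # 1-based incl. header
            fields: dict = {}
            for col, canonical in columns.items():
                text = raw.get(col)
                if text is None or text.strip() == "" or text.strip() == schema.na_token:
                    continue
                text = text.strip()
                if canonical in ("female_taxon", "male_taxon", "replicate_id"):
                    fields[canonical] = text
                elif canonical in ("ovules_fertilized", "fruit_set", "recorded_48h"):
                    fields[canonical] = _parse_bool(text, i, canonical)
                elif canonical in ("pollen_score", "seed_count", "seeds_sown", "seeds_germinated"):
                    value = _parse_num(text, i, canonical, float)
                    if value != int(value):
                        raise ValidationError(
                            f"row {i}: field {canonical!r}: expected integer, got {text!r}"
                        )
                    fields[canonical] = int(value)
                else:
                    fields[canonical] = _parse_num(text, i, canonical)
            if "female_taxon" not in fields or "male_taxon" not in fields:
                raise ValidationError(f"row {i}: missing female_taxon/male_taxon")
            fields.setdefault("replicate_id", str(i - 1))
            record = CrossRecord(**fields)
            if record.recorded_48h and not schema.allow_48h:
                raise ValidationError(
                    f"row {i}: 48 h post-pollination record not admitted "
                    "(set schema.allow_48h to accept and tag it)"
                )
            try:
                record.validate()
            except ValidationError as exc:
                if schema.lenient and not record.fruit_set and (
                    record.fruit_weight is not None or record.seed_count is not None
                ):
                    logger.warning(
                        "row %d: fruit fields present without fruit set; coerced to missing", i
                    )
                    record = replace(record, fruit_weight=None, seed_count=None)
                    record.validate()
                else:
                    raise ValidationError(f"row {i}: {exc}") from None
            records.append(record)
    if not records:
        raise ValidationError(f"{path}: no data rows")
    logger.info("read %d cross records from %s", len(records), path)
    return records


def _mean(values: Sequence[float]) -> float | None:
    return sum(values) / len(values) if values else None


def aggregate_crosses(records: Iterable[CrossRecord]) -> list[CrossSummary]:
    """Aggregate records into one :class:`CrossSummary` per directed pair.

    Means are taken over non-missing values; the germination rate pools
    seeds over all records (total germinated / total sown). The output is
    sorted by (female, male) and therefore invariant to record order.
    """
    groups: dict[tuple[str, str], list[CrossRecord]] = defaultdict(list)
    for record in records:
        groups[(record.female_taxon, record.male_taxon)].append(record)
    summaries = []
    for (female, male), group in sorted(groups.items()):
        scores = [r.pollen_score for r in group if r.pollen_score is not None]
        weights = [r.fruit_weight for r in group if r.fruit_weight is not None]
        seed_counts = [r.seed_count for r in group if r.seed_count is not None]
        seed_weights = [r.seed_weight for r in group if r.seed_weight is not None]
        sown = sum(r.seeds_sown for r in group)
        germinated = sum(r.seeds_germinated for r in group)
        modal = None
        if scores:
            counts = Counter(scores)
            best = max(counts.values())
            # ties resolved toward the lower score (earlier arrest)
            modal = min(s for s, c in counts.items() if c == best)
        summary = CrossSummary(
            female_taxon=female,
            male_taxon=male,
            n_pollinations=len(group),
            mean_pollen_score=_mean(scores),
            modal_pollen_score=modal,
            n_pollen_scored=len(scores),
            any_ovules_fertilized=any(r.ovules_fertilized for r in group)
            or any(r.pollen_score == 4 for r in group),
            fruit_set_fraction=sum(r.fruit_set for r in group) / len(group),
            mean_fruit_weight=_mean(weights),
            mean_seed_count=_mean(seed_counts),
            mean_seed_weight=_mean(seed_weights),
            germination_rate=(germinated / sown) if sown > 0 else None,
            total_seeds_sown=sown,
        )
        if all(
            v is None
            for v in (
                summary.mean_pollen_score,
                summary.mean_fruit_weight,
                summary.mean_seed_count,
                summary.germination_rate,
            )
        ) and summary.fruit_set_fraction == 0:
            logger.warning(
                "pair %s x %s: all stage values missing beyond fruit set", female, male
            )
        summaries.append(summary)
    return summaries


def classify_crossability(
    summary: CrossSummary, self_summary: CrossSummary | None = None
) -> CrossabilityIndex:
    """Assign the ordinal 1-8 crossability level for one directed cross.

    Levels 5-8 (pre-zygotic pollen-tube arrest) are decided by the modal
    pollen score across replicates, ties resolved toward the more severe
    (higher) level. Levels 1-4 rank post-zygotic outcomes from fully
    fertile progeny down to non-germinating seeds. Insufficient inputs
    yield an explicit undetermined result, never a silent default.
    """
    fertilized = summary.any_ovules_fertilized
    has_fruit = summary.fruit_set_fraction > 0
    if not has_fruit:
        modal = summary.modal_pollen_score
        if modal is not None and modal < 4:
            # modal arrest site decides even if the odd tube fertilized an
            # ovule; ci_matrix flags such cells as fertilized-but-failed
            return CrossabilityIndex(
                _ARREST_LEVEL[modal], fertilized_but_failed=fertilized
            )
        if modal == 4 or fertilized:
            # fertilization happened but no fruit: nothing can germinate
            return CrossabilityIndex(4)
        return CrossabilityIndex(None, reason="no fruit and no pollen-tube scores")
    # fertilization (or fruit) happened: post-zygotic levels 1-4
    germination = summary.germination_rate
    if has_fruit and germination is None and summary.total_seeds_sown == 0:
        germination = 0.0 if summary.mean_seed_count is not None else None
    if germination is None:
        return CrossabilityIndex(None, reason="germination outcome unknown")
    if germination == 0:
        return CrossabilityIndex(4)
    fertility = summary.hybrid_fertility
    if fertility == "unknown":
        if summary.is_self:
            fertility = "fertile"
        else:
            return CrossabilityIndex(
                None, reason="germinating seeds but hybrid fertility unknown"
            )
    if fertility == "fully_sterile":
        return CrossabilityIndex(3)
    if summary.is_self and fertility == "fertile":
        return CrossabilityIndex(1)
    if fertility == "fertile" and germination is not None and germination >= 0.9:
        # intraspecific fully fertile cross
        if _same_species(summary.female_taxon, summary.male_taxon):
            return CrossabilityIndex(1)
    return CrossabilityIndex(2)


def _same_species(a: str, b: str) -> bool:
    """Accession labels like ANG and ANG' denote one species."""
    return a.rstrip("'*") == b.rstrip("'*")


def ci_to_pollen_scale(level: int) -> int:
    """Map a crossability level to the 0-4 pollen-progression scale.

    Pre-zygotic levels invert onto the arrest scale (8 -> 0, 7 -> 1,
    6 -> 2, 5 -> 3); post-zygotic levels 1-4 all map to 4 (tubes reach and
    fertilize the ovules).
    """
    if level not in _CI_TO_POLLEN:
        raise ValidationError(f"crossability level must be in 1-8, got {level!r}")
    return _CI_TO_POLLEN[level]


def ci_matrix(
    summaries: Iterable[CrossSummary],
) -> tuple[list[str], dict[tuple[str, str], CrossabilityIndex]]:
    """Classify every directed cross; returns (taxa, {(female, male): CI})."""
    summaries = list(summaries)
    selfs = {s.female_taxon: s for s in summaries if s.is_self}
    taxa = sorted({s.female_taxon for s in summaries} | {s.male_taxon for s in summaries})
    cells = {}
    for summary in summaries:
        ci = classify_crossability(summary, selfs.get(summary.female_taxon))
        if ci.level is not None and ci.level >= 5 and summary.any_ovules_fertilized:
            ci = CrossabilityIndex(ci.level, fertilized_but_failed=True)
        cells[(summary.female_taxon, summary.male_taxon)] = ci
    return taxa, cells


def write_ci_matrix(
    taxa: Sequence[str],
    cells: Mapping[tuple[str, str], CrossabilityIndex],
    tsv_path: str | Path,
    json_path: str | Path | None = None,
) -> None:
    """Write the CI matrix as taxa x taxa TSV plus optional per-cell JSON."""
    with open(tsv_path, "w") as out:
        out.write("female\\male\t" + "\t".join(taxa) + "\n")
        for female in taxa:
            row = [female]
            for male in taxa:
                ci = cells.get((female, male))
                if ci is None or ci.level is None:
                    row.append("NA")
                else:
                    row.append(str(ci.level) + ("*" if ci.fertilized_but_failed else ""))
            out.write("\t".join(row) + "\n")
    if json_path is not None:
        payload = {
            f"{f}x{m}": {
                "level": ci.level,
                "fertilized_but_failed": ci.fertilized_but_failed,
                "reason": ci.reason,
            }
            for (f, m), ci in sorted(cells.items())
        }
        Path(json_path).write_text(json.dumps(payload, indent=2))


def write_summaries(summaries: Iterable[CrossSummary], path: str | Path) -> None:
    """Write cross summaries as TSV (missing values as NA)."""
    fields = [
        "female_taxon", "male_taxon", "n_pollinations", "mean_pollen_score",
        "modal_pollen_score", "fruit_set_fraction", "mean_fruit_weight",
        "mean_seed_count", "mean_seed_weight", "germination_rate",
        "hybrid_fertility",
    ]
    with open(path, "w") as out:
        out.write("\t".join(fields) + "\n")
        for s in summaries:
            row = []
            for name in fields:
                value = getattr(s, name)
                if value is None:
                    row.append("NA")
                elif isinstance(value, float):
                    row.append(f"{value:.6g}")
                else:
                    row.append(str(value))
            out.write("\t".join(row) + "\n")
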