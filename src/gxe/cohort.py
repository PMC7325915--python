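"""Cohort data model and delimited-table IO for matched case-control studies.

The unit of analysis is the matched stratum: one case plus 1-3 controls
matched on age band, sex and recruiting center.  Genotypes are stored as
unordered allele pairs and dichotomized under a dominant model (carrier of
at least one variant allele vs homozygous reference).  Drug exposure is
derived from dated intake events relative to a per-subject index date using
a closed etiological window (default 7 days, including the index date);
events after the index date never count as exposure.
"""

from __future__ import annotations

import datetime as _dt
import io
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "SnpInfo",
    "SubjectRecord",
    "CohortData",
    "ExposureProfile",
    "SchemaError",
    "ValidationError",
    "GenotypeError",
    "read_cohort_table",
    "write_cohort_table",
    "apply_exclusions",
    "code_dominant",
    "derive_exposure",
    "STANDARD_EXCLUSION_RULES",
]

MISSING_TOKENS = {"", "NA", "NaN", "nan", "None", "."}

#: covariates carried as plain columns when present in the input table
KNOWN_COVARIATES = (
    "bmi_class",
    "arthrosis",
    "h_pylori",
    "gi_history",
    "info_source",
    "n_interviews",
    "reliability",
    "nsaid_non_aspirin",
    "ppi",
    "antiaggregant",
    "anticoagulant",
)


class SchemaError(ValueError):
    """A required column is absent or the schema mapping is inconsistent."""


class ValidationError(ValueError):
    """The table violates a cohort-level invariant (e.g. duplicate ids)."""


class GenotypeError(ValueError):
    """A genotype call contains an allele not in the SNP catalog."""


@dataclass(frozen=True)
class SnpInfo:
    """Catalog entry for one biallelic SNP: reference and variant allele."""

    snp_id: str
    ref: str
    alt: str

    def alleles(self) -> set[str]:
        return {self.ref, self.alt}


@dataclass
class SubjectRecord:
    subject_id: str
    stratum_id: str
    is_case: int
    center: str
    period: str
    age: float | None
    sex: str
    bmi_class: str | None
    index_date: _dt.date | None
    drug_events: list[tuple[str, _dt.date]]
    genotypes: dict[str, tuple[str, str] | None]
    covariates: dict[str, object]
    ancestry_flag: str = "white"

    def __post_init__(self) -> None:
        if self.is_case not in (0, 1):
            raise ValidationError(
                f"is_case must be 0/1, got {self.is_case!r} for {self.subject_id}"
            )
        rel = self.covariates.get("reliability")
        if rel is not None and not (0 <= float(rel) <= 10):
            raise ValidationError(
                f"reliability must lie in [0, 10], got {rel!r} for {self.subject_id}"
            )


@dataclass
class CohortData:
    """Validated subject-level cohort with its SNP catalog and exclusion log."""

    subjects: list[SubjectRecord]
    snp_catalog: list[SnpInfo]
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)

    def strata(self) -> dict[str, list[SubjectRecord]]:
        out: dict[str, list[SubjectRecord]] = {}
        for s in self.subjects:
            out.setdefault(s.stratum_id, []).append(s)
        return out

    def snp(self, snp_id: str) -> SnpInfo:
        for s in self.snp_catalog:
            if s.snp_id == snp_id:
                return s
        raise KeyError(f"unknown SNP {snp_id!r}")

    @property
    def n_strata(self) -> int:
        return len({s.stratum_id for s in self.subjects})


@dataclass(frozen=True)
class ExposureProfile:
    subject_id: str
    exposed: int
    window_days: int = 7


# ---------------------------------------------------------------------------
# parsing helpers


def _parse_date(tok: str) -> _dt.date:
    return _dt.date.fromisoformat(tok.strip())


def _parse_genotype(tok: str) -> tuple[str, str] | None:
    tok = tok.strip()
    if tok in MISSING_TOKENS:
        return None
    sep = "/" if "/" in tok else "|"
    parts = tok.split(sep)
    if len(parts) != 2 or not all(parts):
        raise ValueError(f"malformed genotype call {tok!r}")
    return (parts[0].strip(), parts[1].strip())


def _format_genotype(call: tuple[str, str] | None) -> str:
    return "" if call is None else f"{call[0]}/{call[1]}"


def _parse_events(tok: str) -> list[tuple[str, _dt.date]]:
    tok = tok.strip()
    if tok in MISSING_TOKENS:
        return []
    out = []
    for ev in tok.split(";"):
        code, date = ev.split(":")
        out.append((code.strip(), _parse_date(date)))
    return out


def _format_events(events: list[tuple[str, _dt.date]]) -> str:
    return ";".join(f"{c}:{d.isoformat()}" for c, d in events)


REQUIRED_COLUMNS = ("subject_id", "stratum_id", "is_case", "center", "index_date")


def read_cohort_table(
    source,
    schema: dict[str, str] | None = None,
    snp_catalog: list[SnpInfo] | None = None,
    sep: str | None = None,
) -> CohortData:
    """Read a delimited (TSV/CSV) subject-level cohort table.

    Parameters
    ----------
    source
        Path or text stream.  The table must have a header row; the
        delimiter is sniffed (tab preferred) unless ``sep`` is given.
    schema
        Optional mapping from canonical column names to the names used in
        the file; identity for columns not mentioned.
    snp_catalog
        Catalog of (snp_id, ref, alt).  If omitted, genotype columns are
        any column whose name starts with ``rs`` and the reference allele
        is inferred as the major allele among non-missing calls.

    Rows that fail type coercion are recorded in ``exclusion_log`` (never
    silently dropped); missing genotype cells stay missing and are never
    treated as wild-type.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "rt") as fh:
            text = fh.read()
    if sep is None:
        header = text.splitlines()[0] if text else ""
        sep = "\t" if "\t" in header else ","
    raw = pd.read_csv(io.StringIO(text), sep=sep, dtype=str, keep_default_na=False)

    schema = schema or {}
    colmap = {canon: schema.get(canon, canon) for canon in raw.columns.union(schema)}
    rename = {v: k for k, v in colmap.items() if v in raw.columns}
    raw = raw.rename(columns=rename)

    for col in REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"required column {col!r} missing from cohort table")

    snp_cols = (
        [s.snp_id for s in snp_catalog]
        if snp_catalog is not None
        else [c for c in raw.columns if c.startswith("rs")]
    )
    for c in snp_cols:
        if c not in raw.columns:
            raise SchemaError(f"genotype column {c!r} missing from cohort table")

    if raw["subject_id"].duplicated().any():
        dup = raw.loc[raw["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValidationError(f"duplicated subject_id {dup!r}")

    subjects: list[SubjectRecord] = []
    log: list[tuple[str, str]] = []
    for _, row in raw.iterrows():
        sid = row["subject_id"]
        try:
            is_case = int(row["is_case"])
            if is_case not in (0, 1):
                raise ValueError("bad_case_code")
        except ValueError:
            log.append((sid, "bad_case_code"))
            continue
        try:
            geno = {c: _parse_genotype(row[c]) for c in snp_cols}
        except ValueError:
            log.append((sid, "bad_genotype"))
            continue
        try:
            age = None if row.get("age", "") in MISSING_TOKENS else float(row["age"])
            idx = (
                None
                if row["index_date"] in MISSING_TOKENS
                else _parse_date(row["index_date"])
            )
            events = _parse_events(row.get("drug_events", ""))
            cov: dict[str, object] = {}
            for name in KNOWN_COVARIATES:
                if name in raw.columns and row[name] not in MISSING_TOKENS:
                    val = row[name]
                    try:
                        cov[name] = float(val) if "." in val else int(val)
                    except ValueError:
                        cov[name] = val
            rec = SubjectRecord(
                subject_id=sid,
                stratum_id=row["stratum_id"],
                is_case=is_case,
                center=row["center"],
                period=row.get("period", ""),
                age=age,
                sex=row.get("sex", ""),
                bmi_class=cov.get("bmi_class"),
                index_date=idx,
                drug_events=events,
                genotypes=geno,
                covariates=cov,
                ancestry_flag=row.get("ancestry_flag", "white") or "white",
            )
        except (ValueError, ValidationError):
            log.append((sid, "bad_field"))
            continue
        subjects.append(rec)

    if snp_catalog is None:
        snp_catalog = _infer_catalog(subjects, snp_cols)

    subjects, log2 = _validate_strata(subjects)
    return CohortData(subjects=subjects, snp_catalog=snp_catalog, exclusion_log=log + log2)


def _infer_catalog(subjects: list[SubjectRecord], snp_cols: list[str]) -> list[SnpInfo]:
    catalog = []
    for snp in snp_cols:
        counts: dict[str, int] = {}
        for s in subjects:
            call = s.genotypes.get(snp)
            if call is not None:
                for a in call:
                    counts[a] = counts.get(a, 0) + 1
        if not counts:
            catalog.append(SnpInfo(snp, "N", "N"))
            continue
        ordered = sorted(counts, key=lambda a: (-counts[a], a))
        ref = ordered[0]
        alt = ordered[1] if len(ordered) > 1 else ref
        catalog.append(SnpInfo(snp, ref, alt))
    return catalog


def _validate_strata(
    subjects: list[SubjectRecord],
) -> tuple[list[SubjectRecord], list[tuple[str, str]]]:
    """Keep only strata with exactly one case, 1-3 controls, one center."""
    log: list[tuple[str, str]] = []
    by_stratum: dict[str, list[SubjectRecord]] = {}
    for s in subjects:
        by_stratum.setdefault(s.stratum_id, []).append(s)
    kept: list[SubjectRecord] = []
    for sid, members in by_stratum.items():
        n_cases = sum(m.is_case for m in members)
        n_controls = len(members) - n_cases
        if n_cases != 1:
            rule = "stratum_no_case" if n_cases == 0 else "stratum_multiple_cases"
        elif not (1 <= n_controls <= 3):
            rule = "stratum_bad_control_count"
        elif len({m.center for m in members}) != 1:
            rule = "stratum_center_mismatch"
        else:
            kept.extend(members)
            continue
        log.extend((m.subject_id, rule) for m in members)
    return kept, log


def write_cohort_table(cohort: CohortData, path_or_stream, sep: str = "\t") -> None:
    """Write a cohort back to a delimited table (round-trip of read_cohort_table)."""
    snp_cols = [s.snp_id for s in cohort.snp_catalog]
    rows = []
    for s in cohort.subjects:
        row = {
            "subject_id": s.subject_id,
            "stratum_id": s.stratum_id,
            "is_case": s.is_case,
            "center": s.center,
            "period": s.period,
            "age": "" if s.age is None else s.age,
            "sex": s.sex,
            "index_date": "" if s.index_date is None else s.index_date.isoformat(),
            "drug_events": _format_events(s.drug_events),
            "ancestry_flag": s.ancestry_flag,
        }
        for name in KNOWN_COVARIATES:
            if name in s.covariates:
                row[name] = s.covariates[name]
        for snp in snp_cols:
            row[snp] = _format_genotype(s.genotypes.get(snp))
        rows.append(row)
    frame = pd.DataFrame(rows)
    if hasattr(path_or_stream, "write"):
        frame.to_csv(path_or_stream, sep=sep, index=False)
    else:
        frame.to_csv(path_or_stream, sep=sep, index=False)


# ---------------------------------------------------------------------------
# exclusion rules


def _rule_unreliable(s: SubjectRecord) -> bool:
    rel = s.covariates.get("reliability")
    return rel is not None and float(rel) == 0


def _rule_non_white(s: SubjectRecord) -> bool:
    return s.ancestry_flag not in ("white", "")


def _rule_prior_ugih_control(s: SubjectRecord) -> bool:
    return s.is_case == 0 and s.covariates.get("gi_history") == "bleeding"


STANDARD_EXCLUSION_RULES = {
    "unreliable_interview": _rule_unreliable,
    "non_white": _rule_non_white,
    "prior_ugih_control": _rule_prior_ugih_control,
}


def apply_exclusions(cohort: CohortData, rules) -> CohortData:
    """Apply subject-level exclusion rules and drop broken strata.

    ``rules`` is an iterable of rule names (keys of
    ``STANDARD_EXCLUSION_RULES``) or ``(name, predicate)`` pairs.  A subject
    matching any rule is excluded and logged with the triggering rule.  If a
    case is excluded its whole stratum is dropped; if all controls of a
    stratum are excluded the stratum is dropped.  Idempotent for a fixed
    rule-set.
    """
    resolved = []
    for r in rules:
        if isinstance(r, str):
            resolved.append((r, STANDARD_EXCLUSION_RULES[r]))
        else:
            resolved.append(tuple(r))

    log = list(cohort.exclusion_log)
    kept: list[SubjectRecord] = []
    for s in cohort.subjects:
        hit = next((name for name, pred in resolved if pred(s)), None)
        if hit is None:
            kept.append(s)
        else:
            log.append((s.subject_id, hit))

    by_stratum: dict[str, list[SubjectRecord]] = {}
    for s in kept:
        by_stratum.setdefault(s.stratum_id, []).append(s)
    final: list[SubjectRecord] = []
    for sid, members in by_stratum.items():
        n_cases = sum(m.is_case for m in members)
        if n_cases != 1 or len(members) - n_cases == 0:
            log.extend((m.subject_id, "stratum_dropped_after_exclusion") for m in members)
            continue
        final.extend(members)
    if not final:
        warnings.warn("all subjects excluded", stacklevel=2)
    return CohortData(subjects=final, snp_catalog=cohort.snp_catalog, exclusion_log=log)


# ---------------------------------------------------------------------------
# derived codings


def code_dominant(call: tuple[str, str] | None, snp: SnpInfo) -> int | None:
    """Dominant carrier coding: 0 = homozygous reference ("wild-type"),
    1 = at least one variant allele ("genetic variation"); missing propagates.

    Symmetric in allele order.
    """
    if call is None:
        return None
    bad = set(call) - snp.alleles()
    if bad:
        raise GenotypeError(
            f"allele(s) {sorted(bad)} not in catalog for {snp.snp_id} "
            f"({snp.ref}>{snp.alt}); call was {call}"
        )
    return int(any(a == snp.alt for a in call)) if snp.ref != snp.alt else 0


def code_codominant(call: tuple[str, str] | None, snp: SnpInfo) -> int | None:
    """Variant-allele count 0/1/2 (codominant coding); missing propagates."""
    if call is None:
        return None
    bad = set(call) - snp.alleles()
    if bad:
        raise GenotypeError(
            f"allele(s) {sorted(bad)} not in catalog for {snp.snp_id}; call {call}"
        )
    return sum(a == snp.alt for a in call)


def derive_exposure(
    subject: SubjectRecord, drug_class: str = "aspirin", window_days: int = 7
) -> ExposureProfile:
    """Binary exposure from dated drug events in a closed etiological window.

    exposed = 1 iff at least one event of ``drug_class`` falls in
    [index_date - window_days, index_date].  Events after the index date are
    ignored (exposure must precede the outcome).
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    if subject.index_date is None:
        raise ValueError(f"subject {subject.subject_id} has no index date")
    lo = subject.index_date - _dt.timedelta(days=window_days)
    hi = subject.index_date
    exposed = any(
        code == drug_class and lo <= date <= hi for code, date in subject.drug_events
    )
    return ExposureProfile(subject.subject_id, int(exposed), window_days)
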