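"""End-to-end orchestration: read -> exclude -> QC -> per-SNP fit ->
interaction -> report.

Each SNP's analysis is complete-case (subjects missing the genotype or a
model covariate are dropped for that SNP only, and the per-SNP subject
count is logged) and isolated: a failure on one SNP is recorded and the run
continues.  All stored values keep full precision; the 2-dp display
rounding happens only at render time.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .cohort import CohortData, code_dominant, code_codominant, derive_exposure, read_cohort_table, apply_exclusions
from .estimation import DesignMatrix, FitError, backward_eliminate, fit_conditional_logistic, screen_covariates
from .hwe import snp_qc_table
from .interaction import JOINT_TERMS, interaction_ci, joint_indicators, knol_table, stratum_ors

__all__ = ["RunConfig", "RunResult", "build_design", "cell_counts", "run_pipeline", "render_report"]

#: covariates the matched model adjusts for by default, when present
DEFAULT_ADJUSTMENT = [
    "age", "bmi_class", "sex", "arthrosis", "h_pylori", "gi_history",
    "info_source", "n_interviews", "reliability", "nsaid_non_aspirin",
    "ppi", "antiaggregant", "anticoagulant",
]


@dataclass
class RunConfig:
    input_path: str | None = None
    schema: dict | None = None
    exclusion_rules: list = field(default_factory=lambda: ["unreliable_interview", "non_white", "prior_ugih_control"])
    snp_ids: list[str] | None = None  # None -> whole catalog
    covariates: list[str] | str = "none"  # 'none' | 'auto' | explicit list
    screen_alpha: float = 0.2
    cie: float = 0.10
    genotype_coding: str = "dominant"
    drug_class: str = "aspirin"
    window_days: int = 7
    mode: str = "conditional"
    ci_method: str = "delta"
    n_boot: int = 2000
    seed: int | None = None
    min_cell: int = 5
    hwe_alpha: float = 0.001
    call_rate_threshold: float = 0.98
    rereference_mode: str = "stratified-refit"
    out_dir: str | None = None
    rounding: int = 2


@dataclass
class RunResult:
    per_snp: dict
    qc_table: list
    exclusion_log: list
    failures: dict
    config: dict
    version: str
    n_strata: int


def _covariate_value(subject, name):
    if name == "age":
        return subject.age
    if name == "sex":
        return subject.sex
    return subject.covariates.get(name)


def build_design(
    cohort: CohortData,
    snp_id: str,
    covariates: list[str] | None = None,
    genotype_coding: str = "dominant",
    drug_class: str = "aspirin",
    window_days: int = 7,
) -> DesignMatrix:
    """Per-SNP design matrix with the three joint-category indicators, the
    marginal exposure/carrier columns (used by stratified refits), and any
    adjustment covariates.

    Complete-case per SNP: subjects with a missing genotype or covariate
    are dropped, then strata no longer holding one case and at least one
    control are dropped.  Categorical (string-valued) covariates are
    expanded to indicator columns against their first level.
    """
    covariates = covariates or []
    snp = cohort.snp(snp_id)
    coder = code_dominant if genotype_coding == "dominant" else code_codominant
    rows, y, stratum, raw_cov = [], [], [], []
    for s in cohort.subjects:
        g = coder(s.genotypes.get(snp_id), snp)
        if g is None:
            continue
        carrier = int(g > 0)
        cov = [_covariate_value(s, c) for c in covariates]
        if any(v is None for v in cov):
            continue
        exposed = derive_exposure(s, drug_class, window_days).exposed
        rows.append(list(joint_indicators(exposed, carrier)) + [exposed, carrier])
        raw_cov.append(cov)
        y.append(s.is_case)
        stratum.append(s.stratum_id)

    terms = list(JOINT_TERMS) + ["exposed", "carrier"]
    X = np.asarray(rows, dtype=float) if rows else np.empty((0, 5))
    # expand covariates, one-hot for string-valued ones
    cov_cols, cov_names = [], []
    for j, name in enumerate(covariates):
        vals = [r[j] for r in raw_cov]
        if any(isinstance(v, str) for v in vals):
            levels = sorted({str(v) for v in vals})
            for lev in levels[1:]:
                cov_cols.append([float(str(v) == lev) for v in vals])
                cov_names.append(f"{name}[{lev}]")
        else:
            cov_cols.append([float(v) for v in vals])
            cov_names.append(name)
    if cov_cols:
        X = np.column_stack([X] + [np.asarray(c) for c in cov_cols])
    terms = terms + cov_names

    y = np.asarray(y, dtype=int)
    stratum = np.asarray(stratum)
    keep = []
    for sid in np.unique(stratum):
        m = stratum == sid
        if y[m].sum() == 1 and m.sum() >= 2:
            keep.append(sid)
    mask = np.isin(stratum, keep)
    return DesignMatrix(X[mask], y[mask], stratum[mask], terms)


def cell_counts(design: DesignMatrix) -> dict[str, tuple[int, int]]:
    """(n_cases, n_controls) per joint category, from the analysis design."""
    e = design.X[:, design.terms.index("exposed")]
    c = design.X[:, design.terms.index("carrier")]
    out = {}
    for cat, (ee, cc) in {
        "ref": (0, 0), "exp-only": (1, 0), "carrier-only": (0, 1), "both": (1, 1),
    }.items():
        m = (e == ee) & (c == cc)
        out[cat] = (int(design.y[m].sum()), int((1 - design.y[m]).sum()))
    return out


def _select_covariates(design: DesignMatrix, config: RunConfig, candidates: list[str]):
    """Apply the screening + change-in-estimate backward elimination policy."""
    exposure_terms = list(JOINT_TERMS)
    screened, screen_log = screen_covariates(design, candidates, alpha=config.screen_alpha)
    if not screened:
        fit = fit_conditional_logistic(design.subset_terms(exposure_terms))
        return fit, {"screened": screened, "screen_log": screen_log, "elimination": []}
    fit, elim_log = backward_eliminate(
        design, exposure_terms, screened, cie=config.cie
    )
    return fit, {"screened": screened, "screen_log": screen_log, "elimination": elim_log}


def analyse_snp(cohort: CohortData, snp_id: str, config: RunConfig):
    """Fit one SNP end to end; returns (StratumORs, InteractionEstimate, meta)."""
    if config.covariates == "auto":
        candidates = [c for c in DEFAULT_ADJUSTMENT
                      if all(_covariate_value(s, c) is not None for s in cohort.subjects[:1])]
        full = build_design(cohort, snp_id, candidates, config.genotype_coding,
                            config.drug_class, config.window_days)
        present = [t for t in full.terms if t not in JOINT_TERMS + ("exposed", "carrier")]
        fit, selection = _select_covariates(full, config, present)
        design = full
    else:
        covs = [] if config.covariates == "none" else list(config.covariates)
        design = build_design(cohort, snp_id, covs, config.genotype_coding,
                              config.drug_class, config.window_days)
        model_terms = list(JOINT_TERMS) + [t for t in design.terms
                                           if t not in JOINT_TERMS + ("exposed", "carrier")]
        if config.mode == "stratified-fixed":
            from .estimation import fit_logistic_fixed_strata

            fit = fit_logistic_fixed_strata(design.subset_terms(model_terms))
        else:
            fit = fit_conditional_logistic(design.subset_terms(model_terms))
        selection = None
    counts = cell_counts(design)
    ors = stratum_ors(fit, snp_id, mode=config.rereference_mode, design=design,
                      cell_n=counts)
    inter = interaction_ci(fit, snp_id, method=config.ci_method, design=design,
                           n_boot=config.n_boot, seed=config.seed)
    meta = {
        "n_strata_used": fit.n_strata_used,
        "n_subjects_used": int(design.X.shape[0]),
        "converged": fit.converged,
        "separation": fit.separation,
        "selection": selection,
        "beta": {t: float(b) for t, b in zip(fit.terms, fit.beta)},
        "loglik": fit.loglik,
    }
    return ors, inter, meta


def run_pipeline(cohort_or_config, config: RunConfig | None = None) -> RunResult:
    """Run every stage over all requested SNPs; per-SNP failures are
    isolated and logged, never fatal.  Deterministic given config + seed."""
    if isinstance(cohort_or_config, CohortData):
        cohort = cohort_or_config
        config = config or RunConfig()
    else:
        config = cohort_or_config
        cohort = read_cohort_table(config.input_path, schema=config.schema)
    if config.exclusion_rules:
        cohort = apply_exclusions(cohort, config.exclusion_rules)

    qc = snp_qc_table(cohort, alpha=config.hwe_alpha,
                      call_threshold=config.call_rate_threshold)
    snp_ids = (config.snp_ids if config.snp_ids is not None
               else [s.snp_id for s in cohort.snp_catalog])
    per_snp, failures = {}, {}
    for snp_id in snp_ids:
        try:
            ors, inter, meta = analyse_snp(cohort, snp_id, config)
            per_snp[snp_id] = {"ors": ors, "interaction": inter, "meta": meta}
        except Exception as e:  # stage isolation
            failures[snp_id] = f"{type(e).__name__}: {e}"
    return RunResult(
        per_snp=per_snp,
        qc_table=qc,
        exclusion_log=list(cohort.exclusion_log),
        failures=failures,
        config=dataclasses.asdict(config),
        version=__version__,
        n_strata=cohort.n_strata,
    )


# ---------------------------------------------------------------------------
# reporting


def _round(x, nd):
    if isinstance(x, float):
        return round(x, nd)
    if isinstance(x, (tuple, list)):
        return type(x)(_round(v, nd) for v in x)
    return x


def result_tables(result: RunResult, min_cell: int = 5):
    pairs = [(v["ors"], v["interaction"]) for v in result.per_snp.values()]
    return knol_table(pairs, min_cell=min_cell)


def render_report(result: RunResult, out_dir: str, formats=("json", "tsv", "md")):
    """Write machine-readable JSON (full precision) plus human-readable TSV
    and Markdown joint-classification tables (rounded for display only)."""
    os.makedirs(out_dir, exist_ok=True)
    nd = result.config.get("rounding", 2)
    tables = result_tables(result, min_cell=result.config.get("min_cell", 5))
    written = []

    if "json" in formats:
        payload = {
            "version": result.version,
            "config": result.config,
            "n_strata": result.n_strata,
            "qc": result.qc_table,
            "failures": result.failures,
            "exclusion_log": result.exclusion_log,
            "results": {
                snp: {
                    "ors": {k: list(v) for k, v in r["ors"].ors.items()},
                    "rereferenced": {k: list(v) for k, v in r["ors"].rereferenced.items()},
                    "cell_n": {k: list(v) for k, v in r["ors"].cell_n.items()},
                    "reri": r["interaction"].reri,
                    "reri_ci": list(r["interaction"].reri_ci),
                    "s": r["interaction"].s,
                    "s_ci": None if r["interaction"].s_ci is None else list(r["interaction"].s_ci),
                    "ap": r["interaction"].ap,
                    "flags": r["interaction"].flags,
                    "meta": r["meta"],
                }
                for snp, r in result.per_snp.items()
            },
        }
        path = os.path.join(out_dir, "results.json")
        with open(path, "wt") as fh:
            json.dump(payload, fh, indent=2, default=str)
        written.append(path)

    header = ["snp_id", "section", "cell", "n_cases", "n_controls", "or", "or_lo",
              "or_hi", "reri", "reri_lo", "reri_hi", "s", "s_lo", "s_hi"]
    if "tsv" in formats:
        path = os.path.join(out_dir, "knol_table.tsv")
        with open(path, "wt") as fh:
            fh.write("\t".join(header) + "\n")
            for section in ("main", "inconclusive"):
                for row in tables[section]:
                    for cell, key in (("ref", None), ("exp-only", "or10"),
                                      ("carrier-only", "or01"), ("both", "or11")):
                        orv = (1.0, "", "") if key is None else row[key]
                        n = row["cell_n"].get(cell, ("", ""))
                        s = row["s"]
                        s_ci = row["s_ci"] or ("", "")
                        vals = [row["snp_id"], section, cell, n[0], n[1],
                                _round(orv[0], nd), _round(orv[1], nd) if key else "",
                                _round(orv[2], nd) if key else "",
                                _round(row["reri"], nd), _round(row["reri_ci"][0], nd),
                                _round(row["reri_ci"][1], nd),
                                "" if s is None else _round(s, nd),
                                _round(s_ci[0], nd), _round(s_ci[1], nd)]
                        fh.write("\t".join(str(v) for v in vals) + "\n")
        written.append(path)

    if "md" in formats:
        path = os.path.join(out_dir, "knol_table.md")
        with open(path, "wt") as fh:
            for section in ("main", "inconclusive"):
                fh.write(f"## {section}\n\n")
                fh.write("| SNP | cell | N cases/controls | OR (95% CI) | RERI (95% CI) | S (95% CI) |\n")
                fh.write("|---|---|---|---|---|---|\n")
                for row in tables[section]:
                    for cell, key in (("ref", None), ("exp-only", "or10"),
                                      ("carrier-only", "or01"), ("both", "or11")):
                        n = row["cell_n"].get(cell, ("?", "?"))
                        if key is None:
                            orcell = "1.00"
                        else:
                            o = row[key]
                            orcell = f"{o[0]:.{nd}f} ({o[1]:.{nd}f}-{o[2]:.{nd}f})"
                        reri_s = (f"{row['reri']:.{nd}f} "
                                  f"({row['reri_ci'][0]:.{nd}f}-{row['reri_ci'][1]:.{nd}f})"
                                  if cell == "ref" else "")
                        if cell == "ref" and row["s"] is not None and row["s_ci"]:
                            s_s = (f"{row['s']:.{nd}f} "
                                   f"({row['s_ci'][0]:.{nd}f}-{row['s_ci'][1]:.{nd}f})")
                        else:
                            s_s = ""
                        fh.write(f"| {row['snp_id']} | {cell} | {n[0]}/{n[1]} | "
                                 f"{orcell} | {reri_s} | {s_s} |\n")
                fh.write("\n")
        written.append(path)
    return written
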