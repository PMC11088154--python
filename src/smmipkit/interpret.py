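"""qPCR relative-quantification copy calls, per-case diagnostic status and
cohort yield/concordance statistics.

Copy-number confirmation uses the comparative-Ct method: RQ =
efficiency^-ΔΔCt, where ΔΔCt = (Ct_target - Ct_reference)_sample -
(Ct_target - Ct_reference)_calibrator and the calibrator carries two copies.
RQ near 0.5, 1 and 1.5 indicates 1, 2 and 3 copies of the target.

Diagnostic status follows the reporting convention that only pathogenic (P)
or likely pathogenic (LP) variants are diagnostic: for an autosomal-
recessive gene a case is diagnosed by a homozygous P/LP variant, two or
more heterozygous P/LP variants (assumed in trans when unphased), a
homozygous CNV, or a heterozygous SNV plus an overlapping heterozygous CNV;
X-linked genes are diagnosed by a hemizygous (or homozygous) P/LP variant.
Exactly one heterozygous P/LP hit in an AR gene is a *partial* finding.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import beta as beta_dist

from .panel import PanelError

PATHOGENIC = {"P", "LP"}
STRATA = ("biochemical", "high_index", "low_index")


@dataclass(frozen=True)
class QpcrRun:
    """Ct quadruple for one sample/assay: target and reference amplicons in
    the sample and in a two-copy calibrator."""

    sample_ct_target: float
    sample_ct_reference: float
    calibrator_ct_target: float
    calibrator_ct_reference: float

    def __post_init__(self) -> None:
        for v in (self.sample_ct_target, self.sample_ct_reference,
                  self.calibrator_ct_target, self.calibrator_ct_reference):
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise PanelError(f"Ct values must be finite and positive, got {v}")

    @property
    def ddct(self) -> float:
        return (self.sample_ct_target - self.sample_ct_reference) - \
            (self.calibrator_ct_target - self.calibrator_ct_reference)


@dataclass(frozen=True)
class RqResult:
    rq: float
    copy_call: str  # "1", "2", "3" or "unclassified"


def rq(run: QpcrRun, efficiency: float = 2.0) -> RqResult:
    """Relative quantity and nearest-band copy call.

    rq = efficiency^-ΔΔCt (perfect doubling per cycle at efficiency 2).
    Bands are half-open: [0.25, 0.75) -> 1 copy, [0.75, 1.25) -> 2,
    [1.25, 1.75) -> 3, anything else unclassified."""
    value = efficiency ** (-run.ddct)
    if 0.25 <= value < 0.75:
        call = "1"
    elif 0.75 <= value < 1.25:
        call = "2"
    elif 1.25 <= value < 1.75:
        call = "3"
    else:
        call = "unclassified"
    return RqResult(rq=value, copy_call=call)


def read_qpcr(path) -> list[tuple[str, QpcrRun]]:
    """Read a qPCR CSV with columns sample, ct_target, ct_reference,
    calibrator_ct_target, calibrator_ct_reference."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append((row["sample"], QpcrRun(
                float(row["ct_target"]), float(row["ct_reference"]),
                float(row["calibrator_ct_target"]),
                float(row["calibrator_ct_reference"]))))
    return out


@dataclass(frozen=True)
class Variant:
    """One reported variant; CNVs carry exon coordinates via start/end."""

    var_id: str
    gene: str
    zygosity: str  # het | hom | hemi
    classification: str  # P | LP | VUS | ...
    is_cnv: bool = False
    chrom: str | None = None
    start: int | None = None
    end: int | None = None


@dataclass
class CaseRecord:
    case_id: str
    suspected_disease: str = ""
    gene: str = ""
    variants: list[Variant] = field(default_factory=list)
    cnv_calls: list[Variant] = field(default_factory=list)
    stratum: str = "biochemical"

    @property
    def all_variants(self) -> list[Variant]:
        return list(self.variants) + list(self.cnv_calls)


def case_status(record: CaseRecord, inheritance_map: dict) -> str:
    """'diagnosed', 'partial' or 'negative' under the gene's inheritance.

    ``inheritance_map`` maps gene -> 'AR' | 'XL'; every gene carrying a
    P/LP variant must be covered.  VUS are never diagnostic."""
    plp = [v for v in record.all_variants if v.classification in PATHOGENIC]
    by_gene: dict[str, list[Variant]] = {}
    for v in plp:
        by_gene.setdefault(v.gene, []).append(v)
    partial = False
    for gene, variants in by_gene.items():
        if gene not in inheritance_map:
            raise PanelError(f"gene {gene} missing from inheritance map")
        mode = inheritance_map[gene]
        homs = [v for v in variants if v.zygosity == "hom"]
        hets = [v for v in variants if v.zygosity == "het"]
        hemis = [v for v in variants if v.zygosity == "hemi"]
        if mode == "XL":
            if hemis or homs:
                return "diagnosed"
            if hets:
                partial = True
            continue
        # autosomal recessive
        if homs:
            return "diagnosed"
        if len(hets) >= 2:
            # compound het assumed in trans when unphased; includes the
            # het SNV + overlapping het CNV configuration
            return "diagnosed"
        if hets:
            partial = True
    return "partial" if partial else "negative"


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval for k successes in n trials."""
    if n == 0:
        return (float("nan"), float("nan"))
    lo = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def cohort_yield(records, inheritance_map=None, statuses=None) -> pd.DataFrame:
    """Stratified diagnostic yield with exact 95% confidence intervals.

    Either precomputed ``statuses`` (case_id -> status) or an
    ``inheritance_map`` for :func:`case_status` must be supplied.  Rows are
    one per stratum plus an 'all' total; empty strata report n=0 and an
    undefined yield."""
    if statuses is None:
        if inheritance_map is None:
            raise PanelError("need statuses or an inheritance_map")
        statuses = {r.case_id: case_status(r, inheritance_map) for r in records}
    rows = []
    strata = [s for s in STRATA if any(r.stratum == s for r in records)]
    for stratum in strata + ["all"]:
        group = records if stratum == "all" else \
            [r for r in records if r.stratum == stratum]
        n = len(group)
        k = sum(statuses[r.case_id] == "diagnosed" for r in group)
        lo, hi = clopper_pearson(k, n)
        rows.append({"stratum": stratum, "n_total": n, "n_diagnosed": k,
                     "yield_pct": 100.0 * k / n if n else float("nan"),
                     "ci_low_pct": 100.0 * lo, "ci_high_pct": 100.0 * hi})
    return pd.DataFrame(rows)


def _variant_in_footprint(v: Variant, footprint) -> bool:
    if v.chrom is None or v.start is None:
        return True  # no coordinates: cannot attribute the miss to coverage
    for iv in footprint:
        if iv.chrom == v.chrom and iv.start < (v.end or v.start + 1) and v.start < iv.end:
            return True
    return False


def concordance(truth, called, footprint=None) -> dict:
    """Case-level concordance of called results against a truth set.

    A case is concordant when every truth variant is recovered by id;
    additional findings in the called set do not break concordance.  When a
    panel ``footprint`` (GenomicInterval list) is given, a missed variant
    lying outside it is annotated with reason ``uncovered_target`` rather
    than ``not_detected``.  Unmatched case ids are an error."""
    truth_by_id = {r.case_id: r for r in truth}
    called_by_id = {r.case_id: r for r in called}
    unmatched = sorted(set(truth_by_id) ^ set(called_by_id))
    if unmatched:
        raise PanelError(f"unmatched case ids: {unmatched}")
    discordant = []
    for cid in sorted(truth_by_id):
        t, c = truth_by_id[cid], called_by_id[cid]
        called_ids = {v.var_id for v in c.all_variants}
        for v in t.all_variants:
            if v.var_id in called_ids:
                continue
            reason = "not_detected"
            if footprint is not None and not _variant_in_footprint(v, footprint):
                reason = "uncovered_target"
            discordant.append({"case_id": cid, "variant_id": v.var_id,
                               "reason": reason})
    bad_cases = {d["case_id"] for d in discordant}
    n = len(truth_by_id)
    return {"n_cases": n, "n_concordant": n - len(bad_cases),
            "pct_concordant": 100.0 * (n - len(bad_cases)) / n if n else float("nan"),
            "discordant": discordant}


# -- case table I/O ----------------------------------------------------------
# TSV columns: case_id, stratum, suspected_disease, gene, variants, cnvs.
# Variant fields are ':'-joined (var_id:gene:zygosity:classification
# [:chrom:start:end]) and variants are ';'-separated.

def _fmt_variant(v: Variant) -> str:
    core = [v.var_id, v.gene, v.zygosity, v.classification]
    if v.chrom is not None:
        core += [v.chrom, str(v.start), str(v.end)]
    return ":".join(core)


def _parse_variant(text: str, is_cnv: bool) -> Variant:
    f = text.split(":")
    chrom, start, end = (f[4], int(f[5]), int(f[6])) if len(f) >= 7 else (None, None, None)
    return Variant(var_id=f[0], gene=f[1], zygosity=f[2], classification=f[3],
                   is_cnv=is_cnv, chrom=chrom, start=start, end=end)


def write_cases(records, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["case_id", "stratum", "suspected_disease", "gene",
                    "variants", "cnvs"])
        for r in records:
            w.writerow([r.case_id, r.stratum, r.suspected_disease, r.gene,
                        ";".join(_fmt_variant(v) for v in r.variants),
                        ";".join(_fmt_variant(v) for v in r.cnv_calls)])


def read_cases(path) -> list[CaseRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(CaseRecord(
                case_id=row["case_id"], stratum=row["stratum"],
                suspected_disease=row.get("suspected_disease", ""),
                gene=row.get("gene", ""),
                variants=[_parse_variant(t, False)
                          for t in row["variants"].split(";") if t],
                cnv_calls=[_parse_variant(t, True)
                           for t in row["cnvs"].split(";") if t]))
    return out
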