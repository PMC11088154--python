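"""smMIP panel data model, I/O and validation.

A panel is an ordered collection of single-molecule molecular inversion
probes (smMIPs).  Each probe carries two targeting arms (extension and
ligation), a random unique molecular barcode (UMB) in its backbone, and a
fixed-length genomic capture target (110 bp by default).  Probes tile each
exon, with adjacent probes on a tile overlapping by a bounded amount
(20-40 bp by default) so no targeted base falls in an unsequenced seam.

All coordinates are 0-based half-open internally.  Panel TSVs are
documented as 0-based half-open; a 1-based inclusive dialect can be
converted at the reader boundary with ``one_based=True``.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

_DNA = set("ACGT")


class PanelError(ValueError):
    """Raised for malformed or invariant-violating panel data."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise PanelError(f"negative start: {self}")
        if self.end <= self.start:
            raise PanelError(f"empty or inverted interval: {self}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def merge_intervals(intervals) -> list[GenomicInterval]:
    """Union of intervals: sorted, overlapping/abutting runs merged."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if out and iv.chrom == out[-1].chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def subtract_intervals(minuend, subtrahend) -> list[GenomicInterval]:
    """Per-chromosome set difference minuend \\ subtrahend."""
    sub = merge_intervals(subtrahend)
    out: list[GenomicInterval] = []
    for iv in merge_intervals(minuend):
        cursor = iv.start
        for s in sub:
            if s.chrom != iv.chrom or s.end <= cursor or s.start >= iv.end:
                continue
            if s.start > cursor:
                out.append(GenomicInterval(iv.chrom, cursor, s.start))
            cursor = max(cursor, s.end)
        if cursor < iv.end:
            out.append(GenomicInterval(iv.chrom, cursor, iv.end))
    return out


@dataclass(frozen=True)
class Probe:
    """One smMIP: targeting arms, capture target, tag length and pooling state.

    ``conc_uM`` is the phosphorylated (capture-competent) concentration in the
    pool; ``unphos_conc_uM`` is unphosphorylated competitor added during
    rebalancing (cannot be extended/ligated, so it suppresses capture of
    over-performing probes).
    """

    probe_id: str
    gene: str
    target: GenomicInterval
    ext_arm: str
    lig_arm: str
    umb_len: int = 5
    conc_uM: float = 0.1
    phosphorylated: bool = True
    unphos_conc_uM: float = 0.0

    def __post_init__(self) -> None:
        for name, arm in (("ext_arm", self.ext_arm), ("lig_arm", self.lig_arm)):
            if not arm or set(arm) - _DNA:
                raise PanelError(f"probe {self.probe_id}: {name} must be non-empty A/C/G/T")
        if self.umb_len < 1:
            raise PanelError(f"probe {self.probe_id}: umb_len must be >= 1")
        if self.conc_uM <= 0:
            raise PanelError(f"probe {self.probe_id}: conc_uM must be > 0")


@dataclass
class Panel:
    """An ordered probe collection plus its tiling geometry constraints."""

    probes: list[Probe] = field(default_factory=list)
    capture_length: int = 110
    min_overlap: int = 20
    max_overlap: int = 40

    def __post_init__(self) -> None:
        if not (0 <= self.min_overlap <= self.max_overlap < self.capture_length):
            raise PanelError(
                "require 0 <= min_overlap <= max_overlap < capture_length, got "
                f"{self.min_overlap}/{self.max_overlap}/{self.capture_length}"
            )
        ids = [p.probe_id for p in self.probes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelError(f"duplicate probe_id(s): {dup}")
        arms = [(p.ext_arm, p.lig_arm) for p in self.probes]
        if len(set(arms)) != len(arms):
            raise PanelError("duplicate (ext_arm, lig_arm) pair; arm pairs must be panel-unique")

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.probes:
            seen.setdefault(p.gene)
        return list(seen)

    def by_id(self, probe_id: str) -> Probe:
        for p in self.probes:
            if p.probe_id == probe_id:
                return p
        raise KeyError(probe_id)


@dataclass(frozen=True)
class GeneModel:
    """Exon/coding structure of one transcript."""

    gene: str
    transcript: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    coding: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise PanelError(f"{self.gene}: strand must be + or -")
        exs = sorted(self.exons)
        if list(self.exons) != exs:
            raise PanelError(f"{self.gene}: exons must be sorted")
        for a, b in zip(exs, exs[1:]):
            if a.overlap_bp(b) > 0:
                raise PanelError(f"{self.gene}: overlapping exons {a} / {b}")
        if subtract_intervals(self.coding, self.exons):
            raise PanelError(f"{self.gene}: coding intervals extend outside exons")

    @property
    def coding_bp(self) -> int:
        return sum(len(iv) for iv in merge_intervals(self.coding))


@dataclass(frozen=True)
class Violation:
    """One tiling-rule finding; ``severity`` 'error' or 'info'."""

    probe_id: str
    rule: str
    detail: str
    severity: str = "error"


PANEL_COLUMNS = [
    "probe_id", "gene", "chrom", "start", "end",
    "ext_arm", "lig_arm", "umb_len", "conc_uM", "phosphorylated", "unphos_conc_uM",
]
_REQUIRED = ["probe_id", "gene", "chrom", "start", "end", "ext_arm", "lig_arm", "conc_uM"]


def read_panel(path, *, capture_length: int = 110, min_overlap: int = 20,
               max_overlap: int = 40, one_based: bool = False) -> Panel:
    """Read a panel TSV (header + one row per probe).

    Coordinates are 0-based half-open unless ``one_based`` converts a
    1-based inclusive dialect at this boundary.  Raises :class:`PanelError`
    with the offending line number on malformed rows, and on duplicate
    probe ids or an empty (header-only) file.
    """
    probes = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise PanelError(f"{path}: empty file")
        missing = [c for c in _REQUIRED if c not in reader.fieldnames]
        if missing:
            raise PanelError(f"{path}: missing required column(s) {missing}")
        for row in reader:
            lineno = reader.line_num
            try:
                start, end = int(row["start"]), int(row["end"])
                if one_based:
                    start -= 1
                probes.append(Probe(
                    probe_id=row["probe_id"],
                    gene=row["gene"],
                    target=GenomicInterval(row["chrom"], start, end),
                    ext_arm=row["ext_arm"].upper(),
                    lig_arm=row["lig_arm"].upper(),
                    umb_len=int(row.get("umb_len") or 5),
                    conc_uM=float(row["conc_uM"]),
                    phosphorylated=str(row.get("phosphorylated", "True")).lower()
                    in ("1", "true", "yes"),
                    unphos_conc_uM=float(row.get("unphos_conc_uM") or 0.0),
                ))
            except (KeyError, ValueError, TypeError) as exc:
                if isinstance(exc, PanelError):
                    raise PanelError(f"{path}:{lineno}: {exc}") from exc
                raise PanelError(f"{path}:{lineno}: malformed row ({exc})") from exc
    if not probes:
        raise PanelError(f"{path}: empty panel (header only)")
    return Panel(probes, capture_length=capture_length,
                 min_overlap=min_overlap, max_overlap=max_overlap)


def write_panel(panel: Panel, path) -> None:
    """Write the panel TSV (deterministic column and row order)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(PANEL_COLUMNS)
        for p in panel:
            w.writerow([p.probe_id, p.gene, p.target.chrom, p.target.start,
                        p.target.end, p.ext_arm, p.lig_arm, p.umb_len,
                        repr(p.conc_uM), p.phosphorylated, repr(p.unphos_conc_uM)])


def write_targets_bed(panel: Panel, path) -> None:
    """BED6 export of probe targets (0-based half-open, native)."""
    with open(path, "w") as fh:
        for p in sorted(panel, key=lambda p: (p.target.chrom, p.target.start)):
            fh.write(f"{p.target.chrom}\t{p.target.start}\t{p.target.end}"
                     f"\t{p.probe_id}\t0\t+\n")


def read_gene_models(exon_bed, coding_bed=None) -> list[GeneModel]:
    """Load gene models from a 6-column exon BED (name = ``gene|transcript``
    or plain gene symbol), optionally with a separate coding BED.  Without a
    coding BED the exons are taken as fully coding."""
    def _load(path):
        rows = {}
        with open(path) as fh:
            for line in fh:
                f = line.rstrip("\n").split("\t")
                if not f[0] or f[0].startswith(("#", "track")):
                    continue
                name = f[3] if len(f) > 3 else "?"
                strand = f[5] if len(f) > 5 else "+"
                rows.setdefault(name, []).append(
                    (GenomicInterval(f[0], int(f[1]), int(f[2])), strand))
        return rows

    exon_rows = _load(exon_bed)
    coding_rows = _load(coding_bed) if coding_bed else exon_rows
    models = []
    for name, items in exon_rows.items():
        gene, _, transcript = name.partition("|")
        exons = tuple(sorted(iv for iv, _ in items))
        strand = items[0][1]
        coding = tuple(sorted(iv for iv, _ in coding_rows.get(name, [])))
        models.append(GeneModel(gene=gene, transcript=transcript or gene,
                                chrom=exons[0].chrom, strand=strand,
                                exons=exons, coding=coding))
    return models


def write_gene_models(models, exon_bed, coding_bed=None) -> None:
    with open(exon_bed, "w") as fh:
        for m in models:
            for iv in m.exons:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}"
                         f"\t{m.gene}|{m.transcript}\t0\t{m.strand}\n")
    if coding_bed:
        with open(coding_bed, "w") as fh:
            for m in models:
                for iv in m.coding:
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}"
                             f"\t{m.gene}|{m.transcript}\t0\t{m.strand}\n")


def validate_tiling(panel: Panel, include_info: bool = False) -> list[Violation]:
    """Check probe targets against the panel's tiling geometry.

    Probes are sorted by (chrom, start); a positive gap between consecutive
    targets starts a new tile (expected between exons, reported as an
    informational ``tiling_gap`` only when ``include_info``).  Within a tile,
    adjacent targets must overlap by ``[min_overlap, max_overlap]`` bp, and
    every target must span exactly ``capture_length`` bp.  Violations are
    data, not exceptions; an empty list means the panel is compliant.
    """
    if not panel.probes:
        raise PanelError("cannot validate an empty panel")
    out: list[Violation] = []
    for p in panel:
        if len(p.target) != panel.capture_length:
            out.append(Violation(p.probe_id, "bad_target_length",
                                 f"target {len(p.target)} bp != {panel.capture_length} bp"))
    ordered = sorted(panel, key=lambda p: (p.target.chrom, p.target.start, p.target.end))
    for a, b in zip(ordered, ordered[1:]):
        if a.target.chrom != b.target.chrom:
            continue
        gap = b.target.start - a.target.end
        if gap > 0:
            if include_info:
                out.append(Violation(b.probe_id, "tiling_gap",
                                     f"{gap} bp gap after {a.probe_id}", severity="info"))
            continue
        ov = -gap
        if ov < panel.min_overlap:
            out.append(Violation(b.probe_id, "overlap_below_min",
                                 f"{ov} bp overlap with {a.probe_id} < {panel.min_overlap}"))
        elif ov > panel.max_overlap:
            out.append(Violation(b.probe_id, "overlap_above_max",
                                 f"{ov} bp overlap with {a.probe_id} > {panel.max_overlap}"))
    if not include_info:
        out = [v for v in out if v.severity == "error"]
    return out


def target_footprint(panel: Panel) -> dict:
    """Merged union of probe targets and its total size in bp."""
    intervals = merge_intervals(p.target for p in panel)
    return {"intervals": intervals, "total_bp": sum(len(iv) for iv in intervals)}


def coding_coverage(panel: Panel, models) -> pd.DataFrame:
    """Per-gene coding-region coverage of the panel footprint.

    ``pct_covered`` = 100 * |coding ∩ footprint| / |coding|.  Genes present
    in the panel but missing a model are warned about and omitted.
    """
    fp = target_footprint(panel)["intervals"]
    by_gene = {m.gene: m for m in models}
    for gene in panel.genes:
        if gene not in by_gene:
            warnings.warn(f"gene {gene} in panel has no gene model; omitted", stacklevel=2)
    rows = []
    for m in models:
        coding = merge_intervals(m.coding)
        coding_bp = sum(len(iv) for iv in coding)
        uncovered = subtract_intervals(coding, fp)
        covered_bp = coding_bp - sum(len(iv) for iv in uncovered)
        rows.append({"gene": m.gene, "coding_bp": coding_bp, "covered_bp": covered_bp,
                     "pct_covered": 100.0 * covered_bp / coding_bp if coding_bp else float("nan"),
                     "uncovered": uncovered})
    return pd.DataFrame(rows, columns=["gene", "coding_bp", "covered_bp",
                                       "pct_covered", "uncovered"])


def with_concentrations(panel: Panel, plan: pd.DataFrame) -> Panel:
    """Return a copy of the panel with pooling concentrations taken from a
    rebalance plan table (columns probe_id, phos_uM, unphos_uM)."""
    lookup = plan.set_index("probe_id")
    probes = []
    for p in panel:
        if p.probe_id in lookup.index:
            row = lookup.loc[p.probe_id]
            probes.append(replace(p, conc_uM=float(row["phos_uM"]),
                                  unphos_conc_uM=float(row["unphos_uM"])))
        else:
            probes.append(p)
    return Panel(probes, capture_length=panel.capture_length,
                 min_overlap=panel.min_overlap, max_overlap=panel.max_overlap)
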