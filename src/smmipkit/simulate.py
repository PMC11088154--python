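"""Synthetic reference, panel design and UMB-tagged smMIP read simulation.

The generator emulates the assay end to end at desk scale: a random toy
genome with a configurable exon/intron layout, a greedy probe tiler that
satisfies the 110-bp / 20-40-bp-overlap geometry, and a molecule-level
capture model.  Per probe and sample, the number of captured molecules is
Poisson with mean ``depth x capture_efficiency x copy_scale x pool_weight``;
each molecule draws a 5-base UMB uniformly from the 4^5 tag space, an allele
for any injected SNV according to zygosity, and a PCR duplicate count
(geometric, mean ``pcr_dup_mean``); per-base sequencing errors are applied
independently to every read copy.  A truth manifest records the injected
variants, the drawn efficiencies and every molecule's tag so downstream
modules can be scored against ground truth.

Capture efficiency is log-normal(0, ``capture_sigma``) per probe, with a
configured fraction of "poor" probes additionally scaled by ``poor_factor``;
this reproduces the long lower tail of per-probe coverage that motivates
pool rebalancing.  Unphosphorylated competitor (added for over-performing
probes by a rebalance plan) multiplies the effective capture weight by
``competitor_effect`` (default 0.5).
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .panel import (GeneModel, GenomicInterval, Panel, PanelError, Probe,
                    write_gene_models, write_panel)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class VariantSpec:
    """One injected variant.  ``kind`` 'snv' or 'cnv'.

    SNV: ``gene``, ``exon_index`` (0-based) and ``offset`` within the exon,
    ``zygosity`` in {het, hom}; ``alt`` base optional (drawn if None).
    CNV: 0-based inclusive ``first_exon``..``last_exon`` and ``copies`` in
    {0, 1, 3} (against a diploid background of 2).
    """

    sample: str
    kind: str
    gene: str
    zygosity: str = "het"
    exon_index: int = 0
    offset: int = 0
    alt: str | None = None
    first_exon: int = 0
    last_exon: int = 0
    copies: int = 1


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the assay being emulated: 110-bp captures with 20-40 bp
    tiling overlap and 20-bp intron flanks, 5-base tags, a 17-sample batch,
    ~200 deduplicated molecules per probe, a duplicate fraction near 38%
    (geometric duplicates, mean 1.6), ~Q30 base error, and log-normal
    per-probe capture efficiency (sigma 0.5).
    """

    seed: int = 0
    n_genes: int = 2
    exons_per_gene: int = 5
    exon_len: int = 150
    intron_len: int = 300
    spacer: int = 300
    flank: int = 20
    capture_length: int = 110
    min_overlap: int = 20
    max_overlap: int = 40
    arm_len: int = 20
    umb_len: int = 5
    depth: float = 200.0
    pcr_dup_mean: float = 1.6
    seq_error_rate: float = 0.001
    capture_sigma: float = 0.5
    frac_poor_probes: float = 0.0
    poor_factor: float = 0.1
    base_conc_uM: float = 0.1
    competitor_effect: float = 0.5
    n_samples: int = 17
    variants: list[VariantSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.exons_per_gene < 1 or self.n_samples < 1:
            raise PanelError("n_genes, exons_per_gene and n_samples must be positive")
        if min(self.exon_len, self.intron_len, self.spacer, self.depth) <= 0:
            raise PanelError("exon_len, intron_len, spacer and depth must be positive")
        if not 0.0 <= self.seq_error_rate <= 0.05:
            raise PanelError("seq_error_rate must lie in [0, 0.05]")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i:02d}" for i in range(self.n_samples)]


@dataclass
class Reference:
    """Toy reference: one contig plus the gene models laid out on it."""

    contig: str
    sequence: str
    models: list[GeneModel]

    def fetch(self, iv: GenomicInterval) -> str:
        if iv.chrom != self.contig:
            raise KeyError(f"contig {iv.chrom} not in reference")
        return self.sequence[iv.start:iv.end]

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.contig}\n")
            for i in range(0, len(self.sequence), 60):
                fh.write(self.sequence[i:i + 60] + "\n")


def expected_contig_length(cfg: SimConfig) -> int:
    """Closed-form contig length for a config: a leading spacer plus, per
    gene, the exon/intron body followed by a spacer."""
    body = cfg.exons_per_gene * cfg.exon_len + (cfg.exons_per_gene - 1) * cfg.intron_len
    return cfg.spacer + cfg.n_genes * (body + cfg.spacer)


def make_reference(cfg: SimConfig) -> Reference:
    """Deterministic (per seed) random genome with the configured layout."""
    rng = np.random.default_rng(cfg.seed)
    n = expected_contig_length(cfg)
    seq = _BASES[rng.integers(0, 4, size=n)].tobytes().decode()
    models = []
    pos = cfg.spacer
    for g in range(cfg.n_genes):
        exons = []
        for e in range(cfg.exons_per_gene):
            exons.append(GenomicInterval("sim1", pos, pos + cfg.exon_len))
            pos += cfg.exon_len
            if e < cfg.exons_per_gene - 1:
                pos += cfg.intron_len
        pos += cfg.spacer
        gene = f"GENE{g + 1}"
        models.append(GeneModel(gene=gene, transcript=f"T_{gene}", chrom="sim1",
                                strand="+", exons=tuple(exons), coding=tuple(exons)))
    return Reference(contig="sim1", sequence=seq, models=models)


def _tile_region(start: int, end: int, capture: int, min_ov: int, max_ov: int):
    """Target start positions tiling [start, end) with the overlap bounds.

    Step between adjacent targets must lie in [capture - max_ov,
    capture - min_ov].  The minimal probe count is used; when the span the
    probes must cover exceeds the region, the surplus is centred so targets
    overhang both region edges symmetrically.
    """
    length = end - start
    if length <= capture:
        mid = start + length // 2
        return [mid - capture // 2]
    step_min, step_max = capture - max_ov, capture - min_ov
    n = 2
    while capture + (n - 1) * step_max < length:
        n += 1
    # choose n-1 integer steps in [step_min, step_max] with sum >= length - capture
    total = max(length - capture, (n - 1) * step_min)
    base, extra = divmod(total, n - 1)
    base = max(base, step_min)
    steps = [min(step_max, base + (1 if i < extra else 0)) for i in range(n - 1)]
    span = capture + sum(steps)
    first = start - (span - length) // 2
    starts = [first]
    for s in steps:
        starts.append(starts[-1] + s)
    return starts


def design_panel(reference: Reference, models=None, *, capture_length: int = 110,
                 min_overlap: int = 20, max_overlap: int = 40, flank: int = 20,
                 arm_len: int = 20, umb_len: int = 5,
                 base_conc_uM: float = 0.1) -> Panel:
    """Greedy tiler: one probe tile per exon +/- ``flank`` bp of intron.

    Arms are the reference sequences immediately flanking each target, so
    read assignment can recover the probe from raw reads.  Arm-pair
    uniqueness is enforced by growing the arms of a colliding probe.
    """
    if capture_length - max_overlap < 1 or min_overlap >= capture_length:
        raise PanelError("impossible tiling constraints")
    models = reference.models if models is None else models
    probes: list[Probe] = []
    seen_arms: set[tuple[str, str]] = set()
    for m in models:
        for ei, exon in enumerate(m.exons):
            region = (max(exon.start - flank, arm_len + 4),
                      min(exon.end + flank, len(reference.sequence) - arm_len - 4))
            starts = _tile_region(region[0], region[1], capture_length,
                                  min_overlap, max_overlap)
            for pi, s in enumerate(starts):
                target = GenomicInterval(reference.contig, s, s + capture_length)
                ext = reference.sequence[s - arm_len:s]
                lig = reference.sequence[target.end:target.end + arm_len]
                grow = 0
                while (ext, lig) in seen_arms and grow < 4:
                    grow += 1
                    ext = reference.sequence[s - arm_len - grow:s]
                    lig = reference.sequence[target.end:target.end + arm_len + grow]
                seen_arms.add((ext, lig))
                probes.append(Probe(
                    probe_id=f"{m.gene}_e{ei + 1}_p{pi + 1}", gene=m.gene,
                    target=target, ext_arm=ext, lig_arm=lig, umb_len=umb_len,
                    conc_uM=base_conc_uM))
    return Panel(probes, capture_length=capture_length,
                 min_overlap=min_overlap, max_overlap=max_overlap)


def probe_exon_map(panel: Panel, models) -> dict[str, tuple[str, int]]:
    """probe_id -> (gene, exon_index) by maximal target/exon overlap."""
    out = {}
    for p in panel:
        best, best_ov = None, -1
        for m in models:
            for ei, exon in enumerate(m.exons):
                ov = p.target.overlap_bp(exon)
                if ov > best_ov:
                    best, best_ov = (m.gene, ei), ov
        out[p.probe_id] = best
    return out


def draw_efficiencies(panel: Panel, cfg: SimConfig,
                      rng: np.random.Generator) -> dict[str, float]:
    """Per-probe capture efficiency: LogNormal(0, sigma), a random fraction
    of probes additionally scaled by ``poor_factor``."""
    eff = np.exp(rng.normal(0.0, cfg.capture_sigma, size=len(panel)))
    if cfg.frac_poor_probes > 0:
        n_poor = int(round(cfg.frac_poor_probes * len(panel)))
        poor_idx = rng.choice(len(panel), size=n_poor, replace=False)
        eff[poor_idx] *= cfg.poor_factor
    return dict(zip(panel.probe_ids, eff.tolist()))


def _copy_scale(spec_list, gene, exon_index) -> float:
    scale = 1.0
    for v in spec_list:
        if v.kind == "cnv" and v.gene == gene and v.first_exon <= exon_index <= v.last_exon:
            scale = v.copies / 2.0
    return scale


def _pool_weight(probe: Probe, cfg: SimConfig) -> float:
    w = probe.conc_uM / cfg.base_conc_uM
    if probe.unphos_conc_uM > 0:
        w *= cfg.competitor_effect
    return w


def _umb_str(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(out)


@dataclass
class Molecule:
    sample: str
    probe_id: str
    mol_id: int
    umb: str
    insert: str
    n_reads: int


def _sample_molecules(panel: Panel, reference: Reference, cfg: SimConfig,
                      efficiencies, sample: str, rng: np.random.Generator,
                      models=None, with_inserts: bool = True) -> list[Molecule]:
    pmap = probe_exon_map(panel, models or reference.models)
    specs = [v for v in cfg.variants if v.sample == sample]
    snvs = []
    model_by_gene = {m.gene: m for m in (models or reference.models)}
    for v in specs:
        if v.kind != "snv":
            continue
        exon = model_by_gene[v.gene].exons[v.exon_index]
        pos = exon.start + v.offset
        ref_base = reference.sequence[pos]
        alt = v.alt or "ACGT"[("ACGT".index(ref_base) + 1) % 4]
        snvs.append((pos, ref_base, alt, v.zygosity))
    tag_space = 4 ** cfg.umb_len
    molecules: list[Molecule] = []
    for probe in panel:
        gene, ei = pmap[probe.probe_id]
        lam = cfg.depth * efficiencies[probe.probe_id] * \
            _copy_scale(specs, gene, ei) * _pool_weight(probe, cfg)
        n_mol = rng.poisson(lam)
        if n_mol == 0:
            continue
        umbs = rng.integers(0, tag_space, size=n_mol)
        dups = rng.geometric(1.0 / cfg.pcr_dup_mean, size=n_mol) \
            if cfg.pcr_dup_mean > 1 else np.ones(n_mol, dtype=int)
        probe_snvs = [s for s in snvs
                      if probe.target.contains(probe.target.chrom, s[0])] \
            if with_inserts else []
        base_insert = reference.fetch(probe.target) if with_inserts else ""
        for i in range(n_mol):
            insert = base_insert
            if with_inserts:
                for pos, _ref, alt, zyg in probe_snvs:
                    carries = zyg == "hom" or rng.random() < 0.5
                    if carries:
                        off = pos - probe.target.start
                        insert = insert[:off] + alt + insert[off + 1:]
            molecules.append(Molecule(sample, probe.probe_id, i,
                                      _umb_str(int(umbs[i]), cfg.umb_len),
                                      insert, int(dups[i])))
    return molecules


def _errorify(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        cur = arr[i]
        choices = [b for b in (b"A", b"C", b"G", b"T") if b != cur]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def simulate_cohort(panel: Panel, reference: Reference, cfg: SimConfig,
                    out_dir=None, models=None) -> dict:
    """Emit per-sample paired FASTQ (gzip) plus a truth manifest.

    Read structure (declared, configurable at the assignment side):
    R1 = ext_arm + insert (5'->3'); R2 = UMB + lig_arm + revcomp(insert).
    Returns ``{"reads": {sample: [(r1_rec, r2_rec), ...]}, "manifest": ...,
    "paths": ...}``; files are written only when ``out_dir`` is given.
    """
    rng = np.random.default_rng(cfg.seed)
    efficiencies = draw_efficiencies(panel, cfg, rng)
    manifest = {"config_seed": cfg.seed,
                "efficiencies": efficiencies,
                "variants": [asdict(v) for v in cfg.variants],
                "samples": {}}
    reads_by_sample: dict[str, list] = {}
    paths = {}
    out_dir = Path(out_dir) if out_dir is not None else None
    for sample in cfg.sample_ids:
        mols = _sample_molecules(panel, reference, cfg, efficiencies, sample,
                                 rng, models=models)
        manifest["samples"][sample] = {
            "n_molecules": len(mols),
            "molecules": [{"probe_id": m.probe_id, "mol_id": m.mol_id,
                           "umb": m.umb, "n_reads": m.n_reads} for m in mols]}
        pairs = []
        probe_by_id = {p.probe_id: p for p in panel}
        for m in mols:
            probe = probe_by_id[m.probe_id]
            for d in range(m.n_reads):
                rid = f"sim:{sample}:{m.probe_id}:{m.mol_id}:{d}"
                r1 = _errorify(probe.ext_arm + m.insert, cfg.seq_error_rate, rng)
                r2 = _errorify(m.umb + probe.lig_arm + revcomp(m.insert),
                               cfg.seq_error_rate, rng)
                pairs.append((rid, r1, r2))
        reads_by_sample[sample] = pairs
        if out_dir is not None:
            out_dir.mkdir(parents=True, exist_ok=True)
            p1 = out_dir / f"{sample}_R1.fastq.gz"
            p2 = out_dir / f"{sample}_R2.fastq.gz"
            with gzip.open(p1, "wt") as f1, gzip.open(p2, "wt") as f2:
                for rid, r1, r2 in pairs:
                    f1.write(f"@{rid}\n{r1}\n+\n{'I' * len(r1)}\n")
                    f2.write(f"@{rid}\n{r2}\n+\n{'I' * len(r2)}\n")
            paths[sample] = (str(p1), str(p2))
    if out_dir is not None:
        reference.write_fasta(out_dir / "reference.fa")
        write_panel(panel, out_dir / "panel.tsv")
        write_gene_models(models or reference.models,
                          out_dir / "exons.bed", out_dir / "coding.bed")
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        paths["manifest"] = str(out_dir / "manifest.json")
    return {"reads": reads_by_sample, "manifest": manifest, "paths": paths}


def simulate_coverage_counts(panel: Panel, reference: Reference, cfg: SimConfig,
                             efficiencies=None, models=None) -> dict:
    """Fast count-level path: per-sample coverage tables without emitting
    reads.  Deduplicated counts are exact distinct-tag counts among the
    drawn molecules, so tag collisions behave as in the full simulation.

    Returns ``{"coverage": {sample: DataFrame}, "efficiencies": {...}}``;
    coverage columns are probe_id, gene, raw, dedup, dup_frac.
    """
    import pandas as pd

    rng = np.random.default_rng(cfg.seed)
    if efficiencies is None:
        efficiencies = draw_efficiencies(panel, cfg, rng)
    out = {}
    for sample in cfg.sample_ids:
        mols = _sample_molecules(panel, reference, cfg, efficiencies, sample,
                                 rng, models=models, with_inserts=False)
        raw: dict[str, int] = {}
        tags: dict[str, set] = {}
        for m in mols:
            raw[m.probe_id] = raw.get(m.probe_id, 0) + m.n_reads
            tags.setdefault(m.probe_id, set()).add(m.umb)
        rows = []
        for p in panel:
            r = raw.get(p.probe_id, 0)
            d = len(tags.get(p.probe_id, ()))
            rows.append({"probe_id": p.probe_id, "gene": p.gene, "raw": r,
                         "dedup": d, "dup_frac": 1.0 - d / r if r else 0.0})
        out[sample] = pd.DataFrame(rows)
    return {"coverage": out, "efficiencies": efficiencies}
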