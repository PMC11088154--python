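"""Read-depth exon CNV calling from per-probe deduplicated coverage.

The caller follows the ExomeDepth family of read-depth methods: probes are
aggregated to exons; for a test sample, a reference set is assembled from
the co-sequenced batch by ranking samples on Pearson correlation of their
count profiles and greedily accumulating them while the estimated
beta-binomial overdispersion of test-versus-reference does not increase.
Each exon's observed count is modelled as beta-binomial in the test total,
with expected fraction taken from the aggregated reference and scaled on
the odds scale by 0.5 / 1 / 1.5 for the deletion / diploid / duplication
states.  A three-state HMM along the exons of each gene (transition
probability to a CNV state 1e-4 by default) is decoded by Viterbi, and
non-diploid segments are reported with a summed log-likelihood-ratio score.
Batches of at least 17 samples are required by default so the expected
fractions are stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import betabinom, chi2, pearsonr

from .panel import Panel, PanelError
from .simulate import probe_exon_map

STATES = ("deletion", "diploid", "duplication")
STATE_FRACTIONS = (0.5, 1.0, 1.5)


@dataclass
class ExonCountMatrix:
    """samples x exons deduplicated molecule counts.

    ``exons`` rows carry (gene, exon_index, chrom, start, end); ``mask``
    flags low-quality exons (zero counts in more than half the samples)."""

    samples: list[str]
    exons: pd.DataFrame
    counts: np.ndarray
    mask: np.ndarray

    def sample_row(self, sample: str) -> np.ndarray:
        return self.counts[self.samples.index(sample)]


@dataclass(frozen=True)
class CnvCall:
    sample: str
    gene: str
    first_exon: int
    last_exon: int
    state: str
    copy_estimate: str
    ratio: float
    score: float


@dataclass
class CnvParams:
    """Tunable constants of the caller, surfaced as config."""

    transition_cnv: float = 1e-4
    stay_cnv: float = 0.9
    state_fractions: tuple = STATE_FRACTIONS
    min_score: float = 0.0
    rho_floor: float = 1e-6
    rho_ceiling: float = 0.2
    min_batch: int = 17
    enforce_min_batch: bool = True


def build_matrix(coverage_by_sample: dict, panel: Panel, models,
                 min_batch: int = 17, enforce_min_batch: bool = True) -> ExonCountMatrix:
    """Aggregate per-probe coverage tables to an exon count matrix.

    Each probe maps to exactly one exon by maximal target overlap.  Exons
    with zero counts in more than 50% of samples are masked as low quality.
    Fewer than ``min_batch`` samples is an error unless explicitly
    overridden (toy tests)."""
    samples = sorted(coverage_by_sample)
    if enforce_min_batch and len(samples) < min_batch:
        raise PanelError(
            f"CNV calling requires a minimum of {min_batch} samples per batch "
            f"for normalization; got {len(samples)}")
    pmap = probe_exon_map(panel, models)
    exon_rows, exon_index = [], {}
    for m in models:
        for ei, iv in enumerate(m.exons):
            exon_index[(m.gene, ei)] = len(exon_rows)
            exon_rows.append({"gene": m.gene, "exon_index": ei, "chrom": iv.chrom,
                              "start": iv.start, "end": iv.end})
    exons = pd.DataFrame(exon_rows)
    counts = np.zeros((len(samples), len(exon_rows)), dtype=np.int64)
    panel_ids = set(panel.probe_ids)
    for si, sample in enumerate(samples):
        cov = coverage_by_sample[sample]
        if set(cov["probe_id"]) != panel_ids:
            raise PanelError(f"sample {sample}: coverage report does not match panel")
        for _, row in cov.iterrows():
            key = pmap[row["probe_id"]]
            if key in exon_index:
                counts[si, exon_index[key]] += int(row["dedup"])
    zero_frac = (counts == 0).mean(axis=0)
    mask = zero_frac > 0.5
    return ExonCountMatrix(samples=samples, exons=exons, counts=counts, mask=mask)


def _z2(obs: np.ndarray, total: int, frac: np.ndarray) -> np.ndarray:
    """Squared standardized residuals of counts against expected fractions."""
    return (obs - total * frac) ** 2 / (total * frac * (1 - frac))


def dispersion_factor(obs: np.ndarray, total: int, frac: np.ndarray,
                      include=None) -> float:
    """Variance-inflation factor of counts against expected fractions.

    For counts x_j ~ BetaBinomial(n, p_j, rho), E[(x-np)^2 / (np(1-p))] =
    1 + (n-1)rho; the mean of the squared standardized residuals estimates
    that factor.  ``include`` restricts the mean to a fixed exon subset
    (used to hold CNV-suspect exons of the test sample out, so they cannot
    dominate comparisons between candidate reference sets)."""
    keep = frac > 0 if include is None else include & (frac > 0)
    if total <= 1 or keep.sum() == 0:
        return 1.0
    return float(_z2(obs[keep], total, frac[keep]).mean())


def estimate_overdispersion(obs: np.ndarray, total: int, frac: np.ndarray,
                            include=None, floor: float = 1e-6,
                            ceiling: float = 0.2) -> float:
    """Method-of-moments beta-binomial rho from :func:`dispersion_factor`,
    clipped to a usable range for the emission model."""
    factor = dispersion_factor(obs, total, frac, include=include)
    if total <= 1:
        return floor
    rho = (factor - 1.0) / (total - 1.0)
    return float(np.clip(rho, floor, ceiling))


_SUSPECT_Z2 = float(chi2.ppf(0.995, 1))
_FACTOR_SLACK = 0.15


def select_reference(test_sample: str, matrix: ExonCountMatrix):
    """Correlation-ranked, overdispersion-guarded reference aggregation.

    Candidates are ranked by Pearson correlation of unmasked count profiles
    with the test sample; the reference is the longest correlation-ranked
    prefix whose aggregated profile keeps the estimated test-vs-reference
    overdispersion within a small slack of its minimum over all prefixes —
    i.e. accumulation continues while the dispersion does not increase, and
    a poorly matched sample at the tail is left out.  Exons where the test
    deviates grossly from the batch median profile (its own candidate CNVs)
    are held out of the dispersion comparison so they cannot mask a bad
    reference.  At least one sample is always selected.  Returns
    ``(ref_ids, expected_counts, rho)`` with ``expected_counts`` the summed
    reference profile."""
    ti = matrix.samples.index(test_sample)
    test = matrix.counts[ti].astype(float)
    use = ~matrix.mask
    total = int(test[use].sum())
    if total == 0:
        raise PanelError(f"sample {test_sample}: all-zero count profile")
    cands = []
    for si, s in enumerate(matrix.samples):
        if si == ti:
            continue
        prof = matrix.counts[si].astype(float)
        if prof[use].std() == 0 or test[use].std() == 0:
            r = 0.0
        else:
            r = pearsonr(test[use], prof[use])[0]
        cands.append((r, s, prof))
    cands.sort(key=lambda t: (-t[0], t[1]))

    # hold the test's CNV-suspect exons out of the dispersion comparison:
    # residuals against the robust (median) batch profile, fixed across
    # prefixes so all candidate references are judged on the same exons
    profs = np.array([p[use] for _, _, p in cands])
    med_frac = np.median(profs / profs.sum(axis=1, keepdims=True), axis=0)
    med_frac = med_frac / med_frac.sum()
    ok = med_frac > 0
    include = np.zeros(use.sum(), dtype=bool)
    include[ok] = _z2(test[use][ok], total, med_frac[ok]) <= _SUSPECT_Z2
    if not include.any():
        include[:] = True

    def factor_of(agg):
        frac = agg[use] / agg[use].sum()
        return dispersion_factor(test[use], total, frac, include=include)

    agg = np.zeros_like(test)
    factors = []
    for r, s, prof in cands:
        agg = agg + prof
        factors.append(factor_of(agg))
    best = min(factors)
    k = max(i for i, f in enumerate(factors)
            if f <= best * (1 + _FACTOR_SLACK)) + 1
    chosen = [s for _, s, _ in cands[:k]]
    agg = np.sum([prof for _, _, prof in cands[:k]], axis=0)
    frac = np.zeros_like(agg, dtype=float)
    frac[use] = agg[use] / agg[use].sum()
    rho = estimate_overdispersion(test[use], total, frac[use], include=include)
    return chosen, agg, rho


def compute_ratios(matrix: ExonCountMatrix, test_sample: str,
                   expected_counts: np.ndarray) -> pd.DataFrame:
    """Per-exon observed/expected coverage ratios for a test sample.

    Expected fraction per exon = reference exon sum / reference total over
    unmasked exons; ratio = observed / (fraction x test total).
    ``log_norm_cov`` is the log of the size-factor-normalized count (for
    the two-panel CNV plot).  Masked exons report NaN."""
    ti = matrix.samples.index(test_sample)
    obs = matrix.counts[ti].astype(float)
    use = ~matrix.mask
    ref_total = expected_counts[use].sum()
    test_total = obs[use].sum()
    frac = np.full(len(obs), np.nan)
    frac[use] = expected_counts[use] / ref_total
    expected = frac * test_total
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(use & (expected > 0), obs / expected, np.nan)
        size_factor = test_total / ref_total if ref_total else np.nan
        log_norm = np.where(use, np.log((obs + 0.5) / size_factor), np.nan)
    df = matrix.exons.copy()
    df["observed"] = obs
    df["expected_fraction"] = frac
    df["obs_exp_ratio"] = ratio
    df["log_norm_cov"] = log_norm
    return df


def _log_emissions(obs: np.ndarray, total: int, frac: np.ndarray, rho: float,
                   state_fractions) -> np.ndarray:
    """Beta-binomial log emission matrix (exons x states).

    State fraction m scales the expected fraction on the odds scale,
    p' = m p / (m p + 1 - p), which equals m p to first order for the small
    per-exon fractions involved while remaining a probability."""
    E = len(obs)
    out = np.full((E, len(state_fractions)), -np.inf)
    for si, m in enumerate(state_fractions):
        p = np.clip(m * frac / (m * frac + (1.0 - frac)), 1e-12, 1 - 1e-12)
        a = p * (1 - rho) / rho
        b = (1 - p) * (1 - rho) / rho
        out[:, si] = betabinom.logpmf(obs, total, a, b)
    return out


def _transition_matrix(p_cnv: float, p_stay: float) -> np.ndarray:
    # states: deletion, diploid, duplication
    t = np.array([
        [p_stay, 1.0 - p_stay - p_cnv, p_cnv],
        [p_cnv, 1.0 - 2 * p_cnv, p_cnv],
        [p_cnv, 1.0 - p_stay - p_cnv, p_stay],
    ])
    return t


def viterbi(log_em: np.ndarray, log_trans: np.ndarray,
            log_init: np.ndarray) -> np.ndarray:
    """Most probable state path for one gene's exon sequence."""
    E, S = log_em.shape
    score = log_init + log_em[0]
    back = np.zeros((E, S), dtype=int)
    for e in range(1, E):
        cand = score[:, None] + log_trans
        back[e] = np.argmax(cand, axis=0)
        score = cand[back[e], np.arange(S)] + log_em[e]
    path = np.zeros(E, dtype=int)
    path[-1] = int(np.argmax(score))
    for e in range(E - 1, 0, -1):
        path[e - 1] = back[e, path[e]]
    return path


def _copy_estimate(state: str, ratio: float) -> str:
    if state == "deletion":
        return "0" if ratio < 0.25 else "1"
    return "3+"


def call_cnvs(matrix: ExonCountMatrix, test_sample: str,
              params: CnvParams | None = None,
              sex: dict | None = None) -> tuple[list[CnvCall], pd.DataFrame]:
    """Call deletions/duplications for one test sample against its batch.

    Returns ``(calls, ratios)``.  When ``sex`` metadata is provided, X-linked
    exons are compared only against same-sex reference samples; otherwise a
    warning is issued for X exons."""
    params = params or CnvParams()
    ref_ids, expected_counts, rho = select_reference(test_sample, matrix)
    if sex is not None:
        same = [s for s in ref_ids if sex.get(s) == sex.get(test_sample)]
        x_exons = matrix.exons["chrom"].astype(str).str.upper().isin(("X", "CHRX"))
        if x_exons.any() and same and len(same) < len(ref_ids):
            idx = [matrix.samples.index(s) for s in same]
            sub = matrix.counts[idx].sum(axis=0).astype(float)
            expected_counts = np.where(x_exons.to_numpy(), sub, expected_counts)
    else:
        x_exons = matrix.exons["chrom"].astype(str).str.upper().isin(("X", "CHRX"))
        if x_exons.any():
            warnings.warn("X-chromosome exons present but no sex metadata; "
                          "expected fractions use the whole reference set",
                          stacklevel=2)
    ratios = compute_ratios(matrix, test_sample, expected_counts)
    use = ~matrix.mask
    obs_all = matrix.counts[matrix.samples.index(test_sample)]
    total = int(obs_all[use].sum())
    rho = max(rho, params.rho_floor)

    log_trans = np.log(_transition_matrix(params.transition_cnv, params.stay_cnv))
    log_init = np.log(np.array([params.transition_cnv,
                                1.0 - 2 * params.transition_cnv,
                                params.transition_cnv]))
    calls: list[CnvCall] = []
    for gene, gdf in ratios.groupby("gene", sort=False):
        gdf = gdf.sort_values("exon_index")
        keep = use[gdf.index.to_numpy()]
        sub = gdf[keep]
        if len(sub) == 0:
            continue
        obs = sub["observed"].to_numpy()
        frac = sub["expected_fraction"].to_numpy()
        log_em = _log_emissions(obs, total, frac, rho, params.state_fractions)
        path = viterbi(log_em, log_trans, log_init)
        diploid = list(params.state_fractions).index(1.0)
        e = 0
        exon_ids = sub["exon_index"].to_numpy()
        while e < len(path):
            if path[e] == diploid:
                e += 1
                continue
            s = e
            while e < len(path) and path[e] == path[s]:
                e += 1
            seg = slice(s, e)
            state = STATES[path[s]]
            score = float((log_em[seg, path[s]] - log_em[seg, diploid]).sum())
            mean_ratio = float(np.nanmean(sub["obs_exp_ratio"].to_numpy()[seg]))
            if score < params.min_score:
                continue
            calls.append(CnvCall(sample=test_sample, gene=gene,
                                 first_exon=int(exon_ids[s]),
                                 last_exon=int(exon_ids[e - 1]), state=state,
                                 copy_estimate=_copy_estimate(state, mean_ratio),
                                 ratio=mean_ratio, score=score))
    return calls, ratios


def calls_to_frame(calls) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls],
                        columns=["sample", "gene", "first_exon", "last_exon",
                                 "state", "copy_estimate", "ratio", "score"])


def plot_cnv(ratios: pd.DataFrame, matrix: ExonCountMatrix, test_sample: str,
             path, calls=()) -> None:
    """Two-panel figure: log-normalized coverage of the test sample against
    the batch (top) and the observed/expected ratio with called exons
    highlighted (bottom)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    use = ~matrix.mask
    x = np.arange(use.sum())
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
    totals = matrix.counts[:, use].sum(axis=1, keepdims=True).astype(float)
    norm = np.log((matrix.counts[:, use] + 0.5) / (totals / totals.mean()))
    for si, s in enumerate(matrix.samples):
        if s == test_sample:
            continue
        ax1.plot(x, norm[si], color="0.8", lw=0.8)
    ax1.plot(x, norm[matrix.samples.index(test_sample)], color="tab:blue", lw=1.5,
             label=test_sample)
    ax1.set_ylabel("log normalised coverage")
    ax1.legend(loc="lower left", frameon=False)
    ratio = ratios.loc[use, "obs_exp_ratio"].to_numpy()
    ax2.plot(x, ratio, "o-", color="0.4", ms=3)
    called = set()
    for c in calls:
        for e in range(c.first_exon, c.last_exon + 1):
            called.add((c.gene, e))
    flags = [tuple(t) in called for t in
             ratios.loc[use, ["gene", "exon_index"]].itertuples(index=False)]
    if any(flags):
        ax2.plot(x[np.array(flags)], ratio[np.array(flags)], "o", color="red", ms=5)
    ax2.axhline(1.0, color="0.7", ls="--", lw=0.8)
    ax2.set_ylabel("observed / expected")
    ax2.set_xlabel("exon (batch order)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
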