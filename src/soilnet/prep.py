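"""OTU-table preparation and per-OTU / per-cluster descriptive statistics.

Covers the abundance-side bookkeeping the network and path analyses sit on:
prevalence/total-read filtering, rarefaction (without replacement), the
centered log-ratio transform, multiply-rarefied Shannon diversity, the
habitat specialisation index

    SI_i = sigma_i / mu_i - sqrt(K / N_i)

(the coefficient of variation of an OTU's reads across samples minus an
under-sampling correction, K habitat classes and N_i the OTU's total reads),
community-weighted mean SI, box-plot-fence classification of clusters into
habitat generalists/specialists, ln-response-ratio enrichment between the
two soils, and OTU overlap counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, EmptyResultError
from .otutable import OtuTable
from .plants import shannon_diversity

logger = logging.getLogger(__name__)

__all__ = [
    "SpecialisationResult",
    "EnrichmentResult",
    "filter_otus",
    "rarefy",
    "multi_rarefied_shannon",
    "clr_transform",
    "specialisation_index",
    "cwm_si",
    "classify_cluster_specialisation",
    "enrichment_ratio_and_classify",
    "otu_overlap",
]

DEFAULT_MIN_TOTAL_READS = 100
DEFAULT_MIN_SAMPLES = 5


@dataclass
class SpecialisationResult:
    """Per-OTU SI with its ingredients, plus per-sample community-weighted means."""

    per_otu: pd.DataFrame  # index otu_id; columns si, sigma, mu, n_reads
    k_habitats: int
    sample_cwm: pd.Series  # per-sample CWM SI (read-weighted)
    excluded_otus: list[str]  # mu == 0 among included samples
    rarefaction_depth: int | None = None


@dataclass
class EnrichmentResult:
    per_otu_ratio: pd.Series  # ln response ratio per OTU
    cluster_labels: dict[int, str]  # enriched-<A>|enriched-<B>|neutral
    fences: pd.DataFrame  # per cluster: median, q1, q3, lower_fence, upper_fence
    habitats: tuple[str, str]


def filter_otus(
    table: OtuTable,
    min_total_reads: int = DEFAULT_MIN_TOTAL_READS,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> OtuTable:
    """Drop rare OTUs: keep total reads >= min_total_reads and presence
    (count > 0) in >= min_samples samples.  Thresholds are inclusive, i.e.
    the exclusions are strict "less than"."""
    if table.n_otus == 0:
        raise DataError("empty OTU table")
    totals = table.counts.sum(axis=0)
    presence = (table.counts > 0).sum(axis=0)
    keep = table.counts.columns[
        (totals >= min_total_reads) & (presence >= min_samples)
    ]
    if len(keep) == 0:
        raise EmptyResultError("all OTUs removed by filtering")
    return table.subset_otus(keep)


def rarefy(table: OtuTable, depth: int | None = None, seed: int = 0) -> OtuTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    ``depth=None`` uses the smallest sample total.  Samples shallower than
    the depth are dropped with a warning.  Seeded and reproducible.
    """
    totals = table.sample_totals()
    if depth is None:
        depth = int(totals.min())
    if depth < 1:
        raise DataError("rarefaction depth must be >= 1")
    keep = totals.index[totals >= depth]
    if len(keep) == 0:
        raise EmptyResultError(f"no sample has >= {depth} reads")
    if len(keep) < table.n_samples:
        dropped = sorted(set(table.sample_ids) - set(keep))
        logger.warning("rarefy: dropping %d samples below depth %d: %s",
                       len(dropped), depth, dropped)
    rng = np.random.default_rng(seed)
    sub = table.subset_samples(keep)
    out = np.empty_like(sub.counts.to_numpy())
    for i, (_, row) in enumerate(sub.counts.iterrows()):
        out[i] = rng.multivariate_hypergeometric(row.to_numpy(), depth)
    counts = pd.DataFrame(out, index=sub.counts.index, columns=sub.counts.columns)
    return OtuTable(counts, sub.habitat, sub.domain, sub.taxonomy)


def multi_rarefied_shannon(
    table: OtuTable, depth: int | None = None, iterations: int = 1000, seed: int = 0
) -> pd.Series:
    """Per-sample Shannon H averaged over repeated rarefactions."""
    if iterations < 1:
        raise DataError("iterations must be >= 1")
    acc: pd.Series | None = None
    retained: pd.Index | None = None
    for it in range(iterations):
        r = rarefy(table, depth, seed=seed + it)
        h = r.counts.apply(lambda row: shannon_diversity(row.to_numpy()), axis=1)
        if acc is None:
            acc, retained = h, r.counts.index
        else:
            acc = acc + h
    assert acc is not None
    return (acc / iterations).reindex(retained)


def clr_transform(table: OtuTable | pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform per sample: ln(x+pc) minus its row mean."""
    counts = table.counts if isinstance(table, OtuTable) else table
    x = counts.to_numpy(dtype=float)
    if pseudocount <= 0 and np.any(x <= 0):
        raise DataError("zero counts require a positive pseudocount")
    logx = np.log(x + pseudocount)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=counts.index, columns=counts.columns)


def specialisation_index(
    table: OtuTable, k_habitats: int | None = None, depth: int | None = None
) -> SpecialisationResult:
    """Habitat specialisation index per OTU on (already rarefied) counts.

    sigma is the sample (ddof=1) standard deviation of reads across all
    samples, mu their mean, N the OTU's total reads.  OTUs with mu = 0 are
    excluded and listed.  The per-sample community-weighted mean uses the
    sample's relative reads of the retained OTUs as weights.
    """
    if table.n_samples == 0:
        raise DataError("no samples")
    K = k_habitats if k_habitats is not None else table.habitat.nunique()
    counts = table.counts.to_numpy(dtype=float)
    mu = counts.mean(axis=0)
    sigma = counts.std(axis=0, ddof=1)
    n_reads = counts.sum(axis=0)
    present = mu > 0
    excluded = [o for o, p in zip(table.otu_ids, present) if not p]
    with np.errstate(divide="ignore", invalid="ignore"):
        si = sigma / mu - np.sqrt(K / n_reads) if K > 0 else sigma / mu
    retained = [o for o, p in zip(table.otu_ids, present) if p]
    per_otu = pd.DataFrame(
        {"si": si, "sigma": sigma, "mu": mu, "n_reads": n_reads},
        index=table.counts.columns,
    ).loc[retained]

    sub = table.counts[per_otu.index]
    weights = sub.div(sub.sum(axis=1).replace(0, np.nan), axis=0)
    sample_cwm = (weights * per_otu["si"]).sum(axis=1)
    return SpecialisationResult(
        per_otu=per_otu,
        k_habitats=K,
        sample_cwm=sample_cwm,
        excluded_otus=excluded,
        rarefaction_depth=depth,
    )


def cwm_si(si: np.ndarray | pd.Series, weights: np.ndarray | pd.Series) -> float:
    """Community-weighted mean: sum(w * si) / sum(w)."""
    w = np.asarray(weights, dtype=float)
    s = np.asarray(si, dtype=float)
    if np.any(w < 0):
        raise DataError("negative weights")
    total = w.sum()
    if total <= 0:
        raise DataError("zero total weight")
    return float((w * s).sum() / total)


def _fences(values: np.ndarray) -> tuple[float, float, float, float, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    return med, q1, q3, q1 - 1.5 * iqr, q3 + 1.5 * iqr


def classify_cluster_specialisation(
    cluster_si: dict[int, np.ndarray], community_mean_si: float
) -> pd.DataFrame:
    """Label clusters generalist / specialist / intermediate by box-plot fences.

    A cluster is a relative habitat generalist when its mean SI lies below the
    community-wide mean and its upper fence (Q3 + 1.5 IQR) does not reach the
    mean; a specialist is the mirror image with the lower fence
    (Q1 - 1.5 IQR) above the mean.
    """
    rows = []
    for cl, vals in sorted(cluster_si.items()):
        v = np.asarray(vals, dtype=float)
        if v.size == 0:
            raise DataError(f"cluster {cl} has no SI values")
        med, q1, q3, lo, hi = _fences(v)
        mean = float(v.mean())
        if mean < community_mean_si and hi < community_mean_si:
            label = "generalist"
        elif mean > community_mean_si and lo > community_mean_si:
            label = "specialist"
        else:
            label = "intermediate"
        rows.append(
            {"cluster": cl, "label": label, "cwm_si": mean, "median": med,
             "q1": q1, "q3": q3, "lower_fence": lo, "upper_fence": hi}
        )
    return pd.DataFrame(rows).set_index("cluster")


def enrichment_ratio_and_classify(
    table: OtuTable,
    partition: dict[str, int],
    pseudocount: float = 1.0,
    habitats: tuple[str, str] | None = None,
) -> EnrichmentResult:
    """Ln response ratio per OTU between habitat-summed (rarefied) counts and
    a fence-based enrichment call per cluster.

    ratio = ln((reads_A + pc) / (reads_B + pc)); a cluster is enriched in A
    when its median ratio is positive and the lower fence stays above zero
    (mirrored for B); otherwise neutral.
    """
    habs = habitats or tuple(sorted(table.habitat.unique()))
    if len(habs) != 2:
        raise DataError(f"need exactly 2 habitats, got {habs}")
    a, b = habs
    mask_a = table.habitat == a
    mask_b = table.habitat == b
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise DataError("habitat with zero samples")
    sums_a = table.counts.loc[mask_a.to_numpy()].sum(axis=0).astype(float)
    sums_b = table.counts.loc[mask_b.to_numpy()].sum(axis=0).astype(float)
    ratio = np.log((sums_a + pseudocount) / (sums_b + pseudocount))

    labels: dict[int, str] = {}
    rows = []
    clusters = sorted(set(partition.values()))
    for cl in clusters:
        otus = [o for o, c in partition.items() if c == cl]
        vals = ratio.loc[otus].to_numpy()
        med, q1, q3, lo, hi = _fences(vals)
        if med > 0 and lo > 0:
            labels[cl] = f"enriched-{a}"
        elif med < 0 and hi < 0:
            labels[cl] = f"enriched-{b}"
        else:
            labels[cl] = "neutral"
        rows.append({"cluster": cl, "median": med, "q1": q1, "q3": q3,
                     "lower_fence": lo, "upper_fence": hi})
    return EnrichmentResult(
        per_otu_ratio=ratio,
        cluster_labels=labels,
        fences=pd.DataFrame(rows).set_index("cluster"),
        habitats=(a, b),
    )


def otu_overlap(table_a: OtuTable, table_b: OtuTable) -> tuple[int, int, int]:
    """(shared, unique to A, unique to B) OTU-id counts, presence = count>0."""
    a = {o for o in table_a.otu_ids if table_a.counts[o].sum() > 0}
    b = {o for o in table_b.otu_ids if table_b.counts[o].sum() > 0}
    return len(a & b), len(a - b), len(b - a)
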