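#!/usr/bin/env python
"""Prokaryote-fungal coupling and its relation to plant community stability.

Per mesocosm, the coupling beta between rank-matched prokaryote and fungal
cluster abundances (top clusters of each domain); the Bonferroni-corrected
cross-domain cluster correlation table; and the mixed-model test of
ln(temporal stability) against coupling with soil as the random factor.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from soilnet.coupling import (
    bonferroni_threshold,
    cluster_correlations,
    coupling_scores,
    stability_coupling_test,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--pairs", type=int, default=9)
    args = parser.parse_args()

    pa = pd.read_csv(args.out / "cluster_abundance_prokaryote.tsv",
                     sep="\t", index_col=0)
    fa = pd.read_csv(args.out / "cluster_abundance_fungal.tsv",
                     sep="\t", index_col=0)
    metrics = pd.read_csv(args.out / "plant_metrics.tsv", sep="\t",
                          index_col="mesocosm_id")

    scores = coupling_scores(pa, fa, n_pairs=args.pairs)
    scores.to_csv(args.out / "coupling_scores.tsv", sep="\t")
    k = int(scores["n_cluster_pairs"].iloc[0])
    print(f"coupling beta over {k} rank-matched cluster pairs: "
          f"mean {scores['beta'].mean():.3f}, range "
          f"[{scores['beta'].min():.3f}, {scores['beta'].max():.3f}]")

    n_clusters = pa.shape[1] + fa.shape[1]
    full, rounded = bonferroni_threshold(0.05, n_clusters)
    table = cluster_correlations(pa, fa, grouping=metrics["sowing_density"],
                                 family_alpha=0.05, denominator="clusters")
    table.to_csv(args.out / "cluster_correlations.tsv", sep="\t", index=False)
    print(f"cross-domain correlations: {table['significant'].sum()} of "
          f"{len(table)} significant at per-test alpha {rounded} "
          f"({n_clusters} clusters)")

    test = stability_coupling_test(metrics["temporal_stability"],
                                   scores["beta"], metrics["soil"])
    report = {"slope": test.slope, "se": test.se, "wald_chi2": test.wald_chi2,
              "p": test.p, "n": test.n}
    (args.out / "stability_coupling.json").write_text(json.dumps(report, indent=1))
    print(f"ln(stability) ~ coupling beta: slope {test.slope:.3f}, "
          f"Wald chi2 {test.wald_chi2:.3f}, p {test.p:.3g} (n = {test.n})")


if __name__ == "__main__":
    main()
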