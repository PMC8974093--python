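"""Consensus positively selected sites from the published per-method scans,
reduction of alleles to PSS, and consensus supertype clustering (5 x 10
seeded K-means/DAPC runs on z-descriptor encodings).

Writes results/consensus_pss.csv and results/supertypes.csv.
"""

from pathlib import Path

import pandas as pd

from midas_mhc.io import load_allele_fasta
from midas_mhc.published import SITE41_EXCLUSION, published_pss_reports
from midas_mhc.selection import consensus_pss, reduce_to_pss
from midas_mhc.supertyping import consensus_supertypes, encode_z

BASE = Path(__file__).resolve().parents[1] / "results"
SIM = BASE / "simulated"
SEED = 20260926


def main() -> None:
    reports = published_pss_reports()
    pss = consensus_pss(reports, min_methods=2, exclude=SITE41_EXCLUSION)
    pd.DataFrame({"site": pss.positions,
                  "n_methods": [pss.support[p] for p in pss.positions]}
                 ).to_csv(BASE / "consensus_pss.csv", index=False)
    print(f"consensus PSS (>=2 of {len(reports)} methods): {pss.positions}")
    print(f"supported by all methods: {pss.supported_by(len(reports))}")

    catalog = load_allele_fasta(SIM / "alleles.fasta")
    reduced, allele_map = reduce_to_pss(catalog, pss)
    print(f"\n{len(catalog)} alleles -> {catalog.unique_translations()} unique "
          f"translations -> {len(reduced)} unique PSS-reduced sequences")

    keys = list(reduced)
    X = encode_z(keys)
    st = consensus_supertypes(X, keys=keys, k_range=range(2, 21),
                              n_batches=5, n_runs_per_batch=10, seed=SEED)
    alleles = st.propagate(allele_map)
    out = pd.DataFrame({
        "allele_id": list(alleles.labels),
        "supertype": [alleles.labels[a] for a in alleles.labels],
        "support": [alleles.support[a] for a in alleles.labels],
    })
    out.to_csv(BASE / "supertypes.csv", index=False)
    sizes = out["supertype"].value_counts().sort_index()
    print(f"consensus K = {st.k}; alleles per supertype: "
          f"{sizes.min()}-{sizes.max()}")
    print(f"mean consensus support: {out['support'].mean():.3f}")


if __name__ == "__main__":
    main()
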