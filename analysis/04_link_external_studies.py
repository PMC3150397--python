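#!/usr/bin/env python
"""Link the signature to external study tables and assign progression clusters.

Generates a synthetic study pack (five androgen-response studies, seven
tumor-progression studies, configurable concordance and missingness, in
place of the non-redistributable published databases), applies the
presence filters (>= 3 of 5 androgen studies, >= 4 of 7 tumor studies),
hierarchically clusters the concordance matrix (1 - centered Pearson,
average linkage) and assigns the four progression clusters from the
androgen direction x metastasis-consensus direction.  Writes the matrix
(CDT style), a Newick dendrogram and the cluster table under
results/crossdb/.
"""

import argparse
from pathlib import Path

import pandas as pd

from arsig import crossdb
from arsig.simulate import generate_study_pack


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--signature", default="results/signature/signature.tsv")
    ap.add_argument("--out", default="results/crossdb")
    ap.add_argument("--concordance", type=float, default=0.85)
    ap.add_argument("--frac-missing", type=float, default=0.25)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    sig = pd.read_csv(args.signature, sep="\t")
    genes = sig.drop_duplicates("symbol")
    pack = generate_study_pack(sig, concordance=args.concordance,
                               frac_missing=args.frac_missing, seed=args.seed)
    tables = crossdb.harmonize_identifiers(pack)

    andro = tables[tables.comparison_class == "androgen_response"]
    tumor = tables[tables.comparison_class != "androgen_response"]
    symbols = genes.symbol.str.upper().tolist()
    in_andro = crossdb.presence_filter(symbols, andro, min_present=3)
    in_tumor = crossdb.presence_filter(symbols, tumor, min_present=4)
    print(f"{len(symbols)} signature genes; {len(in_andro)} present in >=3/5 "
          f"androgen studies, {len(in_tumor)} in >=4/7 tumor studies")

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    kept = [g for g in symbols if g in set(in_andro) or g in set(in_tumor)]
    mat = crossdb.build_concordance_matrix(kept, tables)
    z, order = crossdb.hierarchical_cluster(mat)
    (out / "dendrogram.nwk").write_text(
        crossdb.linkage_to_newick(z, mat.index.tolist()) + "\n")
    crossdb.export_cdt(mat, out / "concordance.cdt", leaf_order=order)

    dirs = genes.assign(symbol=genes.symbol.str.upper())
    dirs = dirs.set_index("symbol")["direction"]
    clusters = crossdb.assign_progression_clusters(dirs.loc[
        [g for g in in_tumor]], tables)
    clusters.to_csv(out / "progression_clusters.tsv", sep="\t", index=False)
    tally = clusters.cluster.astype(str).value_counts().sort_index()
    print("\nprogression-cluster membership "
          "(1: repressed/up in mets ... 4: induced/up in mets):")
    print(tally.to_string())


if __name__ == "__main__":
    main()
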