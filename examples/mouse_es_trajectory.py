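"""Optional real-data example: mouse embryonic stem cell differentiation.

Reconstructs the differentiation trajectory of mouse ES cells induced
toward primitive endoderm (RamDA-seq time course, GEO accession
GSE98664).  This script is NOT part of the test suite: it needs a network
connection to download the expression matrix (~400 cells x ~150k
features) and takes several minutes end to end.

Steps:
  1. download + load the count matrix (cells x genes),
  2. keep high-variance genes, log2-normalize,
  3. reduce to a few dimensions (PCA here; any reduction works --
     pass pre-reduced coordinates with --no-reduce on the CLI),
  4. fit the embedding tree and compute pseudotime from a 0 h cell.

Usage:  python examples/mouse_es_trajectory.py --workdir /tmp/gse98664
"""

import argparse
import pathlib
import sys
import urllib.request

GEO_URL = ("https://www.ncbi.nlm.nih.gov/geo/download/"
           "?acc=GSE98664&format=file&file="
           "GSE98664%5Ftpm%5Fsailfish%5FmESpre%2Etxt%2Egz")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--workdir", type=pathlib.Path, required=True)
    ap.add_argument("--dims", type=int, default=4)
    ap.add_argument("--n-genes", type=int, default=2000,
                    help="high-variance genes to keep")
    args = ap.parse_args()
    args.workdir.mkdir(parents=True, exist_ok=True)

    raw = args.workdir / "gse98664_tpm.txt.gz"
    if not raw.exists():
        print(f"downloading {GEO_URL} ...", file=sys.stderr)
        urllib.request.urlretrieve(GEO_URL, raw)

    import numpy as np
    import pandas as pd

    from stsearch import (Dataset, ExpressionMatrix, STSConfig,
                          compute_pseudotime, log2_normalize, reduce_pca,
                          run_sts)

    # rows are genes in the GEO file; transpose to cells x genes
    tpm = pd.read_csv(raw, sep="\t", index_col=0).T
    counts = ExpressionMatrix(tpm.to_numpy(float),
                              [str(i) for i in tpm.index],
                              [str(c) for c in tpm.columns])
    normed = log2_normalize(counts)
    order = np.argsort(normed.counts.var(axis=0))[::-1][:args.n_genes]
    kept = ExpressionMatrix(normed.counts[:, order], normed.cell_ids,
                            [normed.gene_ids[i] for i in order])
    data: Dataset = reduce_pca(kept, args.dims)

    tree, trace = run_sts(data, STSConfig(seed=0))
    tree.to_json(args.workdir / "tree.json")

    # cells are named by time point in this series; root at a 0 h cell
    root = next(c for c in data.cell_ids if "00h" in c or "0h" in c)
    result = compute_pseudotime(data, tree, root)
    result.to_csv(args.workdir / "pseudotime.csv")
    print(f"fitted tree with {tree.n_vertices} vertices; "
          f"pseudotime written to {args.workdir / 'pseudotime.csv'}")


if __name__ == "__main__":
    main()
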