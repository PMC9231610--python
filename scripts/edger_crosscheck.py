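"""Developer cross-check: compare tmm_factors against edgeR::calcNormFactors.

Requires an R installation with edgeR; not part of the test suite because R
availability is not guaranteed everywhere the tests run. The in-suite oracle
for TMM is the independent brute-force implementation in tests/.

Usage: python scripts/edger_crosscheck.py [seed]
"""

from __future__ import annotations

import subprocess
import sys
import tempfile

import numpy as np
import pandas as pd

from ctprop.preprocess import CountMatrix, tmm_factors


def main(seed: int = 11) -> None:
    rng = np.random.default_rng(seed)
    n_genes, n_samp = 200, 6
    base = rng.lognormal(3, 1.5, n_genes)
    lib = np.array([1.0, 1.5, 0.7, 2.0, 1.2, 0.9])
    mu = np.outer(base, lib)
    mu[-20:, 0] *= 4  # composition bias
    counts = rng.poisson(rng.gamma(10.0, mu / 10.0))
    df = pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)],
                      columns=[f"s{j}" for j in range(n_samp)])
    py = tmm_factors(CountMatrix(df, dataset="x")).to_numpy()
    with tempfile.TemporaryDirectory() as d:
        df.to_csv(f"{d}/c.tsv", sep="\t")
        r = subprocess.run(
            ["Rscript", "-e",
             f'x<-as.matrix(read.delim("{d}/c.tsv",row.names=1));'
             'f<-edgeR::calcNormFactors(x);cat(sprintf("%.12f\\n",f))'],
            capture_output=True, text=True, check=True)
    rf = np.array([float(v) for v in r.stdout.split()])
    diff = np.abs(py - rf).max()
    print("python:", np.round(py, 10))
    print("edgeR :", np.round(rf, 10))
    print("max abs diff:", diff)
    if diff > 1e-6:
        raise SystemExit(f"TMM factors diverge from edgeR by {diff:.2e}")
    print("OK (within 1e-6)")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 11)
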