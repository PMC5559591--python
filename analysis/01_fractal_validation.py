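#!/usr/bin/env python
"""Validate the box-counting estimators on patterns of known dimension.

Findings this script reports:
* on the order-4 Sierpinski carpet scanned with an aligned power-of-3 grid,
  the estimator returns the similarity dimension log8/log3 to machine
  precision;
* under the default randomized 12-grid/12-size protocol the same carpet
  reads ~0.19 low — the finite-order prefractal is locally space-filling at
  2 px and saturates the lattice above ~28 px, so the global least-squares
  slope mixes in dimension-2 end behavior;
* random Cantor dust (b=3, levels=4) scanned at its natural power-of-3
  sizes recovers D = log(9p)/log 3 to within about 0.01-0.03 on average.

Writes results/fractal_validation.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from necrofract.fractal import ScanProtocol, build_scan, fd_from_scan
from necrofract.synthetic import make_random_cantor, make_sierpinski_carpet


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    rows = []
    carpet = make_sierpinski_carpet(4)
    target = np.log(8) / np.log(3)
    fd_exact = fd_from_scan(build_scan(carpet, ScanProtocol(box_sizes=(3, 9, 27), n_grids=1)))[1]
    rows.append({"pattern": "carpet4", "scan": "aligned_pow3", "target": target, "fd": fd_exact})
    fd_proto = fd_from_scan(build_scan(carpet, ScanProtocol(seed=args.seed)))[1]
    rows.append({"pattern": "carpet4", "scan": "default_protocol", "target": target, "fd": fd_proto})

    for p in (1 / 3, 2 / 3, 8 / 9):
        d = np.log(9 * p) / np.log(3)
        fds = [
            fd_from_scan(
                build_scan(
                    make_random_cantor(3, p, 4, seed=args.seed * 1000 + k),
                    ScanProtocol(box_sizes=(3, 9, 27), n_grids=1),
                )
            )[1]
            for k in range(20)
        ]
        rows.append(
            {"pattern": f"cantor_p{p:.3f}", "scan": "aligned_pow3_mean20", "target": d, "fd": float(np.mean(fds))}
        )

    table = pd.DataFrame(rows)
    table["error"] = table["fd"] - table["target"]
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "fractal_validation.csv", index=False)
    print(table.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
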