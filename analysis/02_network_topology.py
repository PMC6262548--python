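#!/usr/bin/env python
"""Characterize the regulatory network's topology: degree distribution,
power-law fits of degree / in-degree / out-degree, and per-kind medians.

Reads the bundle written by 01_simulate_data.py; writes results/topology.json.

Usage: python analysis/02_network_topology.py [--bundle results/bundle]
"""

import argparse
import json
from pathlib import Path

from trireg.network import topology_summary
from trireg.synthetic import read_bundle


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--bundle", default="results/bundle")
    ap.add_argument("--out", default="results/topology.json")
    args = ap.parse_args()

    net = read_bundle(args.bundle).network
    ts = topology_summary(net)

    payload = {
        "nodes": len(net),
        "edges": len(net.edges),
        "degree_one_fraction": ts.degree_one_fraction,
        "kind_medians": ts.kind_medians.to_dict(),
        "fits": {
            which: None if fit is None else
            {"a": fit.a, "b": fit.b, "r2": fit.r2}
            for which, fit in ts.fits.items()
        },
    }
    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    Path(args.out).write_text(json.dumps(payload, indent=2))

    print(f"{payload['degree_one_fraction']:.1%} of nodes have degree one")
    for which, fit in ts.fits.items():
        if fit:
            print(f"{which}: y = {fit.a:.1f} * x^{fit.b:.2f} (R^2 = {fit.r2:.3f})")
    print("median in/out-degree by kind:")
    print(ts.kind_medians.to_string())
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
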