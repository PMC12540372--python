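"""Produce the packaged reference parameter set.

Runs the summary-level weighted least-squares calibration
(:func:`glimtwin.calibration.fit_reference`) and writes
``src/glimtwin/data/reference_parameters.json`` plus the fitted CTP-C
severity factor into ``src/glimtwin/data/reference_calibration.json``.

Usage: python scripts/calibrate_reference.py [--n-starts N] [--seed S]
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from glimtwin import calibration
from glimtwin.parameters import ParameterSet

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "src" / "glimtwin" / "data"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-starts", type=int, default=4)
    ap.add_argument("--seed", type=int, default=42)
    args = ap.parse_args()

    base = ParameterSet()
    best, f_ctp_c, records = calibration.fit_reference(
        base, n_starts=args.n_starts, seed=args.seed)

    feats = calibration.summary_features(best, f_ctp_c, rtol=1e-8)
    targets = calibration.summary_targets().set_index("feature")
    print(f"fitted CTP-C severity factor: {f_ctp_c:.4f}")
    print(f"{'feature':24s} {'fit':>10s} {'target':>10s} {'dev%':>7s}")
    for k in targets.index:
        tgt = float(targets.loc[k, "target"])
        print(f"{k:24s} {feats[k]:10.3f} {tgt:10.3f} "
              f"{100 * (feats[k] / tgt - 1):6.1f}%")

    DATA.mkdir(parents=True, exist_ok=True)
    best.to_json(DATA / "reference_parameters.json")
    with open(DATA / "reference_calibration.json", "w") as fh:
        json.dump({
            "f_ctp_c": f_ctp_c,
            "n_starts": args.n_starts,
            "seed": args.seed,
            "features": feats,
            "per_start_cost": [r.final_cost for r in records],
        }, fh, indent=1, default=float)
    print(f"wrote {DATA / 'reference_parameters.json'}")


if __name__ == "__main__":
    main()
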