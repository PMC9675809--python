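#!/usr/bin/env python
"""Sensor-level cluster summary.

Reads the combined-planar-gradiometer cluster tables written by
02_run_pipeline.py (memorized vs novel per piece; pointwise paired t at
alpha = 0.01, space-time cluster Monte-Carlo correction at alpha = 0.001
with 1000 permutations) and prints the significant clusters in the layout
of the published sensor tables: size, distinct channels, time interval,
Monte-Carlo p, direction.
"""

from pathlib import Path

import pandas as pd

RUN_DIR = Path("results/run")


def main() -> None:
    for piece in ("tonal", "atonal"):
        path = RUN_DIR / f"sensor_clusters_{piece}.tsv"
        if not path.exists():
            print(f"{path} missing — run analysis/02_run_pipeline.py first")
            return
        tab = pd.read_csv(path, sep="\t")
        sig = tab[tab["significant"] == True] if len(tab) else tab  # noqa: E712
        print(f"\n=== {piece}: {len(sig)} significant sensor clusters ===")
        if len(sig):
            cols = ["cluster_number", "size", "n_channels_or_voxels",
                    "time_interval_s", "p_value", "direction"]
            print(sig[cols].to_string(index=False))


if __name__ == "__main__":
    main()
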