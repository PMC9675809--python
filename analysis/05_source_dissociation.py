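#!/usr/bin/env python
"""Slow-band source-space dissociation check.

Runs the memorized-vs-novel slow-band (0.1-1 Hz) analysis for both pieces
on one simulated cohort and asks whether the built-in ground truth is
recovered: memorized-tonal should show memorized>novel clusters with
majority labels in the memory regions (hippocampus, cingulate) at tone
windows 3-5, and memorized-atonal should show right-auditory
memorized>novel clusters at every window. Cluster tables go to
results/source_dissociation/.
"""

from pathlib import Path

from meg_seqmem.pipeline import slow_band_dissociation

OUT = Path("results/source_dissociation")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    res = slow_band_dissociation(SEED)
    for piece, tab in res["tables"].items():
        tab.to_csv(OUT / f"source_clusters_slow_{piece}.tsv", sep="\t", index=False)
        sig = tab[(tab["significant"] == True)  # noqa: E712
                  & (tab["direction"] == "memorized>novel")]
        print(f"\n=== {piece}: significant memorized>novel clusters ===")
        if len(sig):
            print(sig[["window", "size", "roi_majority", "p_value"]]
                  .to_string(index=False))
    print(f"\ndissociation recovered: {res['recovered']}")


if __name__ == "__main__":
    main()
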