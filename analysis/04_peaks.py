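#!/usr/bin/env python
"""Accessibility peak sets: consensus, gained/lost/common, size filter.

Two-step construction: merge the later time point's peaks with baseline
into disjoint consensus regions, then label each region by overlap —
gained (later only), lost (baseline only), common (both).  Regions
shorter than 300 bp are discarded from gained/lost before TE analysis.
"""

from pathlib import Path

from tereawaken import io as tio
from tereawaken.config import PipelineConfig
from tereawaken.peaks import filter_min_length, gained_lost, merge_peaks

BASE = Path(__file__).resolve().parent.parent / "results"
SIM = BASE / "simdata"


def main() -> None:
    cfg = PipelineConfig()
    p0 = tio.read_peaks(SIM / "peaks_D0.narrowPeak", "D0")
    pt = tio.read_peaks(SIM / "peaks_t.narrowPeak", "t")
    consensus = merge_peaks(pt, p0)
    gained, lost, common = gained_lost(consensus, pt, p0)
    n_before = len(gained)
    gained_f = filter_min_length(gained, cfg.min_peak_len)
    lost_f = filter_min_length(lost, cfg.min_peak_len)
    for name, ps in [("consensus", consensus), ("gained", gained_f),
                     ("lost", lost_f), ("common", common)]:
        tio.write_peaks(ps, BASE / f"peaks_{name}.bed")
    print(f"consensus regions: {len(consensus)} "
          f"(from {len(pt)} later + {len(p0)} baseline peaks)")
    print(f"gained {len(gained)}, lost {len(lost)}, common {len(common)} "
          f"(partition check: {len(gained) + len(lost) + len(common) == len(consensus)})")
    print(f">= {cfg.min_peak_len} bp filter: gained {n_before} -> {len(gained_f)}")
    print("beds -> peaks_consensus/gained/lost/common.bed")


if __name__ == "__main__":
    main()
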