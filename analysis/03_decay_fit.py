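#!/usr/bin/env python
"""Fit the nucleosome-phased flanking peaks to exponential decays.

Fits the default targeted dataset (parameter recovery against generative
truth), then contrasts two enzyme conditions generated with amplitude ratio
1.4 and decay-constant ratio 1.25 — the in-silico analogue of comparing a
smaller, more efficient tethered enzyme against a reference.  Writes
results/decay_fits.tsv and results/decay_contrast.tsv.
"""

from pathlib import Path

import pandas as pd

from fibermod.decay_fit import (compare_fits, find_flank_peaks, fit_decay,
                                period_averaged_heights)
from fibermod.fiber_sim import (FiberSimConfig, expected_amplitude,
                                simulate_dataset)
from fibermod.profile_agg import aggregate_at_sites, smooth
from fibermod.regions import read_bed

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"
SEED = 1


def recovery_fit(bam, sites, cfg):
    prof = aggregate_at_sites(bam, sites, 1200, "a", 225)
    peaks = find_flank_peaks(smooth(prof, 50))
    return fit_decay(period_averaged_heights(prof, peaks, cfg.nrl)), peaks


def main():
    RESULTS.mkdir(exist_ok=True)
    cfg = FiberSimConfig(seed=SEED)
    sites = read_bed(SCRATCH / "pair" / "target_sites.bed")
    fit, peaks = recovery_fit(SCRATCH / "pair" / "target.bam", sites, cfg)
    linker_fraction = (cfg.nrl - cfg.core_len) / cfg.nrl
    a_truth = cfg.p_bound * expected_amplitude(cfg, 225) * linker_fraction
    rows = [{"condition": "default", "a": fit.a, "lam": fit.lam, "c": fit.c,
             "se_a": fit.se_a, "se_lam": fit.se_lam, "n_peaks": fit.n_peaks,
             "a_truth": a_truth, "lam_truth": cfg.lam_teth}]
    print(f"default fit: a={fit.a:.4f} (truth {a_truth:.4f}), "
          f"lambda={fit.lam:.5f}/bp (truth {cfg.lam_teth:.5f}), "
          f"{fit.n_peaks} peaks")

    fits = []
    for tag, A, lam in (("efficient", 0.7, 1 / 160),
                        ("reference", 0.5, 1 / 200)):
        c = FiberSimConfig(seed=SEED + (1 if tag == "efficient" else 2),
                           A_teth=A, lam_teth=lam)
        out = simulate_dataset(c, "target", SCRATCH / f"contrast_{tag}")
        f, _ = recovery_fit(out["bam"], out["sites"], c)
        fits.append(f)
        rows.append({"condition": tag, "a": f.a, "lam": f.lam, "c": f.c,
                     "se_a": f.se_a, "se_lam": f.se_lam,
                     "n_peaks": f.n_peaks, "a_truth": None,
                     "lam_truth": lam})
    contrast = compare_fits(*fits)
    pd.DataFrame(rows).to_csv(RESULTS / "decay_fits.tsv", sep="\t",
                              index=False)
    pd.DataFrame([contrast]).to_csv(RESULTS / "decay_contrast.tsv", sep="\t",
                                    index=False)
    print(f"contrast: amplitude ratio {contrast['amplitude_ratio']:.2f} "
          f"(generated 1.40), decay-constant ratio "
          f"{contrast['lambda_ratio']:.2f} (generated 1.25) — the efficient "
          f"condition labels ~40% higher with a ~25% tighter distribution")


if __name__ == "__main__":
    main()
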