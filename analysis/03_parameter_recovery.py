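"""Check that measured agreement recovers the simulator's analytic values.

Sweeps a grid of per-exam sensitivity s and between-exam correlation rho,
simulates 5000 pairs per cell, measures PPA/CPPA at a fully permissive
threshold, and compares with the closed forms
PPA = 100(rho + (1-rho)s) and CPPA = 100·PPA/(200-PPA).
Writes the comparison table to results/parameter_recovery.csv.
"""

from pathlib import Path

import pandas as pd

from cadrepro import (
    SimConfig,
    expected_cppa,
    expected_ppa,
    match_dataset,
    paired_confusion,
    simulate_paired_detections,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def measure(s: float, rho: float, seed: int):
    ds, _ = simulate_paired_detections(
        SimConfig(n_pairs=5000, sensitivity=s, correlation=rho, seed=seed)
    )
    matches = match_dataset(ds)
    mi = [matches[p.initial.exam_id] for p in ds.pairs]
    mf = [matches[p.followup.exam_id] for p in ds.pairs]
    conf = paired_confusion(ds.pairs, mi, mf, tau=0.0)
    return conf, ds.n_lesions


def main() -> None:
    rows = []
    for i, s in enumerate([0.6, 0.8, 0.95]):
        for j, rho in enumerate([0.0, 0.5, 0.9]):
            conf, n = measure(s, rho, seed=1000 + 10 * i + j)
            rows.append({
                "s": s, "rho": rho, "n_lesions": n,
                "ppa_measured": round(conf.ppa, 2),
                "ppa_expected": round(expected_ppa(s, rho), 2),
                "cppa_measured": round(conf.cppa, 2),
                "cppa_expected": round(expected_cppa(s, rho), 2),
            })
    df = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "parameter_recovery.csv", index=False)
    print(df.to_string(index=False))
    max_gap = (df.ppa_measured - df.ppa_expected).abs().max()
    print(f"\nlargest |measured - analytic| PPA gap: {max_gap:.2f} points "
          f"(Monte-Carlo noise at ~5500 lesions per cell)")
    print(f"wrote {OUT}/parameter_recovery.csv")


if __name__ == "__main__":
    main()
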