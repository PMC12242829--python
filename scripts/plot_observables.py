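#!/usr/bin/env python
"""Plot the observable CSVs written by `spherofiber run` / `observe`.

Usage: python scripts/plot_observables.py OUT_DIR [--save figs.png]

Panels: <Q_n>(t), cell displacement, normalized mean linker force, spheroid
shape index, radial density-ratio and Omega_rr profiles, and the final-state
histograms (cell shape index, V_i/V0, bond strain) when present.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("out_dir", type=Path)
    ap.add_argument("--save", type=Path, default=None)
    args = ap.parse_args()
    d = args.out_dir

    fig, axes = plt.subplots(3, 3, figsize=(13, 10))
    series = pd.read_csv(d / "series.csv")
    t = series["t"]
    for ax, col, label in [
            (axes[0, 0], "qn", r"$\langle Q_n\rangle$"),
            (axes[0, 1], "mean_disp", r"$|\Delta r_{cell}|/R_s$"),
            (axes[0, 2], "mean_linker_force_norm", "linker force (norm.)"),
            (axes[1, 0], "spheroid_shape", r"$A_{sp}/V_{sp}^{2/3}$"),
            (axes[1, 1], "mean_volume_ratio", r"$\langle V_i/V_0\rangle$")]:
        if col in series:
            ax.plot(t, series[col])
            ax.set_xlabel("t [t0]")
            ax.set_ylabel(label)
    prof_path = d / "radial_profiles.csv"
    if prof_path.exists():
        prof = pd.read_csv(prof_path)
        r = 0.5 * (prof["r_lo"] + prof["r_hi"])
        axes[1, 2].plot(r, prof["density_ratio"], "o-")
        axes[1, 2].set_xlabel("R")
        axes[1, 2].set_ylabel(r"$\rho_f/\rho_i$")
        axes[2, 0].plot(r, prof["omega_rr"], "o-")
        axes[2, 0].axhline(1 / 3, ls="--", c="k")
        axes[2, 0].set_xlabel("R")
        axes[2, 0].set_ylabel(r"$\Omega_{rr}$")
    for ax, name in [(axes[2, 1], "hist_shape_index"),
                     (axes[2, 2], "hist_bond_strain")]:
        p = d / f"{name}.csv"
        if p.exists():
            h = pd.read_csv(p)
            ax.bar(0.5 * (h["bin_lo"] + h["bin_hi"]),
                   h["density"], width=h["bin_hi"] - h["bin_lo"])
            ax.set_xlabel(name.replace("hist_", ""))
            ax.set_ylabel("density")
    fig.tight_layout()
    target = args.save or (d / "observables.png")
    fig.savefig(target, dpi=130)
    print(target)


if __name__ == "__main__":
    main()
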