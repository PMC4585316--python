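"""Calibrate the shared LR1 adjustment factors for all cell types.

The three cell types share one ionic model and differ only in gNa_max
(PCM 13.5, LE_SCM 4.5, HE_SCM 11.5 mS/cm2).  This script grid-searches the
shared slow-inward (Ca2+) conductance scale, its inactivation-kinetics
scale and the time-dependent K+ conductance scale so that

  * the PCM action potential duration (APD90) is ~100 ms, making
    refractoriness compatible with 300-ms pacing and with the measured
    effective refractory periods (~120-140 ms), and
  * the isolated-cell upstroke velocities of the two SCM types fall within
    the experimental bands 107 +/- 13 V/s (LE) and 230 +/- 20 V/s (HE).

Run:  python scripts/calibrate_celltypes.py
The selected factors are frozen into strandcv.lr1.DEFAULT_CELL_TYPES.
"""

import itertools

from strandcv import lr1

APD_TARGET = 100.0
DVDT_BANDS = {"LE_SCM": (107.0, 13.0), "HE_SCM": (230.0, 20.0)}
GNA = {"PCM": 13.5, "LE_SCM": 4.5, "HE_SCM": 11.5}

GSI_GRID = [0.4, 0.6, 0.8, 1.0, 1.2]
GK_GRID = [4.0, 5.0, 6.0, 7.0, 8.0, 10.0]
TAU_F_GRID = [0.5, 1.0]


def evaluate(gsi, tau_f, gk):
    metrics = {}
    for name, gna in GNA.items():
        p = lr1.CellTypeParams(name, gna, gsi_scale=gsi, tau_f_scale=tau_f,
                               gk_scale=gk)
        tr = lr1.simulate_single_cell(p, beats=1)
        metrics[name] = (
            lr1.max_upstroke_velocity(tr),
            lr1.apd90(tr),
            tr.elicited,
        )
    return metrics


def main():
    rows = []
    for gsi, tau_f, gk in itertools.product(GSI_GRID, TAU_F_GRID, GK_GRID):
        m = evaluate(gsi, tau_f, gk)
        if not all(v[2] for v in m.values()):
            continue
        apd_pcm = m["PCM"][1]
        feasible = all(
            abs(m[t][0] - mu) <= sd for t, (mu, sd) in DVDT_BANDS.items()
        ) and apd_pcm == apd_pcm  # APD defined
        cost = abs(apd_pcm - APD_TARGET) + 0.1 * sum(
            abs(m[t][0] - mu) for t, (mu, _) in DVDT_BANDS.items()
        )
        rows.append((feasible, cost, gsi, tau_f, gk, m))
        print(
            f"gsi={gsi:4.1f} tau_f={tau_f:3.1f} gk={gk:5.1f} | "
            f"APD90(PCM)={apd_pcm:6.1f} "
            f"dVdt LE={m['LE_SCM'][0]:6.1f} HE={m['HE_SCM'][0]:6.1f} "
            f"PCM={m['PCM'][0]:6.1f} {'ok' if feasible else '--'}"
        )

    best = min((r for r in rows if r[0]), key=lambda r: r[1], default=None)
    if best is None:
        print("\nNo grid point satisfied all constraints.")
        return
    _, cost, gsi, tau_f, gk, m = best
    print("\nSelected shared factors:")
    print(f"  gsi_scale={gsi}  tau_d_scale=1.0  tau_f_scale={tau_f}  gk_scale={gk}")
    for name in GNA:
        dv, apd, _ = m[name]
        print(f"  {name}: dV/dt_max={dv:.1f} V/s  APD90={apd:.1f} ms")


if __name__ == "__main__":
    main()
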