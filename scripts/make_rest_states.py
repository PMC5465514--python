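"""Regenerate the packaged quiescent states in cardioviz/_rest_states.py.

Relaxes each transmural cell class (endo, mid, epi) unstimulated for 40 s
at dt = 0.02 ms from the published paced steady-state initial conditions,
then freezes the terminal states as module constants so simulations start
from a reproducible rest without per-run burn-in.

Run from the repository root:  python scripts/make_rest_states.py
"""

import pathlib
import sys

import numpy as np

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from cardioviz import _tnnp06 as tp          # noqa: E402
from cardioviz._kernel import NPAR, PAR_IDX, step_cells  # noqa: E402

RELAX_MS = 40_000.0
DT = 0.02

CLASSES = ("endo", "mid", "epi")


def main() -> None:
    n = len(CLASSES)
    S = np.tile(tp.PUBLISHED_INITIAL.reshape(-1, 1), (1, n)).astype(np.float64)
    P = np.empty((NPAR, n))
    for col, cls in enumerate(CLASSES):
        g = {
            "g_Na": tp.G_NA, "g_K1": tp.G_K1, "g_Kr": tp.G_KR,
            "g_to": tp.G_TO[cls], "g_Ks": tp.G_KS[cls], "g_CaL": tp.G_CAL,
            "k_NaCa": tp.KNACA, "P_NaK": tp.P_NAK, "g_pCa": tp.G_PCA,
            "g_pK": tp.G_PK, "g_bCa": tp.G_BCA, "g_bNa": tp.G_BNA,
        }
        for name, row in PAR_IDX.items():
            P[row, col] = g[name]
    is_endo = np.array([cls == "endo" for cls in CLASSES], dtype=np.uint8)
    istim = np.zeros(n)
    ext = np.zeros(n)

    n_steps = int(round(RELAX_MS / DT))
    for _ in range(n_steps):
        step_cells(S, P, is_endo, istim, ext, DT, 1.0)

    lines = [
        '"""Packaged quiescent states (generated by scripts/make_rest_states.py).',
        "",
        "Each entry is the state vector (layout of cardioviz._tnnp06.VAR_NAMES)",
        "after a 40 s unstimulated relaxation at dt = 0.02 ms from the published",
        'paced steady-state initial conditions of the corresponding cell class."""',
        "",
        "REST_STATES = {",
    ]
    for col, cls in enumerate(CLASSES):
        vals = ",\n        ".join(repr(float(v)) for v in S[:, col])
        lines.append(f'    "{cls}": (\n        {vals},\n    ),')
    lines.append("}")
    out = pathlib.Path(__file__).resolve().parents[1] / "src" / "cardioviz" / "_rest_states.py"
    out.write_text("\n".join(lines) + "\n")
    for col, cls in enumerate(CLASSES):
        print(f"{cls}: Vm = {S[0, col]:.4f} mV")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
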