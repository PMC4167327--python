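"""Optional plotting helper for fitted curves and pace of decline.

Excluded from test guarantees; requires matplotlib (the ``plot`` extra).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def plot_curves_and_pace(curves: pd.DataFrame, path: str | Path) -> Path:
    """Two-panel figure: fitted mean rates (top) and pace of decline (bottom)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax0, ax1) = plt.subplots(2, 1, figsize=(7, 7), sharex=True)
    for race, g in curves.groupby("race"):
        ax0.plot(g["year"], g["rate_fitted"], label=str(race))
        ax1.plot(g["year"], g["pace"], label=str(race))
    ax0.set_ylabel("mortality rate per 100,000")
    ax1.set_ylabel("pace of decline (per year)")
    ax1.set_xlabel("year")
    ax0.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
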