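"""Heat-map rendering of sweep tables (optional; requires matplotlib)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

MEASURES = ("Total_MI", "H_sys", "A", "A_star", "nC", "NTIC")


def render_sweep_heatmaps(
    df: pd.DataFrame, outdir: str | Path, measures=MEASURES
) -> list[Path]:
    """One PNG per measure: a row of heat maps over (alpha_S, beta_S),
    one panel per gamma_S value.  Returns the written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gammas = sorted(df.gamma_S.unique())
    alphas = sorted(df.alpha_S.unique())
    betas = sorted(df.beta_S.unique())
    written = []
    for measure in measures:
        fig, axes = plt.subplots(
            1, len(gammas), figsize=(3.2 * len(gammas), 3.2), squeeze=False
        )
        vmax = float(df[measure].abs().max()) or 1.0
        vmin = float(min(df[measure].min(), 0.0))
        for ax, g in zip(axes[0], gammas):
            sub = df[df.gamma_S == g].pivot(
                index="beta_S", columns="alpha_S", values=measure
            )
            im = ax.imshow(
                sub.values, origin="lower", aspect="auto",
                extent=(min(alphas), max(alphas), min(betas), max(betas)),
                vmin=vmin, vmax=vmax, cmap="viridis",
            )
            ax.set_title(f"gamma_S = {g:g}")
            ax.set_xlabel("alpha_S")
        axes[0][0].set_ylabel("beta_S")
        fig.colorbar(im, ax=axes[0], label=f"{measure} [bits]", shrink=0.85)
        path = outdir / f"sweep_{measure}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
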