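"""Plot helpers: bull's-eye polar charts and Bland-Altman agreement plots."""

from __future__ import annotations

import numpy as np

from .quantify import N_SEGMENTS, AgreementStats, BullsEye


def plot_bullseye(be: BullsEye, ax=None, cmap: str = "viridis"):
    """Render a 12-segment bull's-eye: VWT on the outer ring, the
    centerline-to-inner-wall distance on the inner ring.

    The anatomical anchors are labelled A (anterior, 0 deg), R, P, L,
    clockwise as viewed from proximal to distal.
    """
    import matplotlib.pyplot as plt
    from matplotlib import cm, colors

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)  # clockwise
    width = 2 * np.pi / N_SEGMENTS
    angles = np.arange(N_SEGMENTS) * width

    def ring(values, inner, outer):
        finite = values[np.isfinite(values)]
        norm = colors.Normalize(
            vmin=float(finite.min()) if finite.size else 0.0,
            vmax=float(finite.max()) if finite.size else 1.0,
        )
        mapper = cm.ScalarMappable(norm=norm, cmap=cmap)
        for ang, v in zip(angles, values):
            color = mapper.to_rgba(v) if np.isfinite(v) else (0.8, 0.8, 0.8, 1.0)
            ax.bar(
                ang + width / 2,
                outer - inner,
                width=width,
                bottom=inner,
                color=color,
                edgecolor="white",
            )
        return mapper

    ring(be.segment_inner_mm, 0.35, 0.65)
    mapper = ring(be.segment_vwt_mm, 0.7, 1.0)
    ax.set_xticks(np.deg2rad([0, 90, 180, 270]))
    ax.set_xticklabels(["A", "R", "P", "L"])
    ax.set_yticks([])
    ax.set_title(f"max VWT {be.max_vwt_mm:.2f} mm")
    return ax, mapper


def plot_bland_altman(x: np.ndarray, y: np.ndarray, stats: AgreementStats, ax=None):
    """Scatter of paired differences against means with the mean difference
    and the mean +/- 1.96 sd limits of agreement as dashed lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ax.scatter((x + y) / 2, x - y, s=14, alpha=0.7)
    for value, style in (
        (stats.mean_diff, "--"),
        (stats.loa_low, ":"),
        (stats.loa_high, ":"),
    ):
        ax.axhline(value, linestyle=style, color="grey")
    ax.set_xlabel("mean of measurements (mm)")
    ax.set_ylabel("difference (mm)")
    return ax
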