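"""Scatter plot of normalized vertebral positions inside the generalized
ellipse (severity by marker symbol, gender by fill)."""

from __future__ import annotations

import numpy as np

# display-only aspect ratio of the generalized ellipse (left-right : ant-post)
ELLIPSE_DISPLAY_RATIO = 1.5

_SEVERITY_MARKERS = {"mild": "o", "medium": "s", "strong": "^"}


def plot_positions(positions, out_path=None, ax=None):
    """Plot (u, v) positions inside the generalized ellipse outline.

    Parameters
    ----------
    positions
        Iterable of dicts with keys u, v and optional severity, gender,
        label.
    out_path
        If given, figure is saved there (format from the extension).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    a, b = ELLIPSE_DISPLAY_RATIO, 1.0
    th = np.linspace(0, 2 * np.pi, 400)
    ax.plot(a * np.cos(th), b * np.sin(th), color="0.3", lw=1)
    ax.axhline(0, color="0.8", lw=0.6)
    ax.axvline(0, color="0.8", lw=0.6)
    for p in positions:
        marker = _SEVERITY_MARKERS.get(p.get("severity"), "o")
        filled = p.get("gender") == "female"
        ax.plot(a * p["u"], b * p["v"], marker=marker, ms=6,
                mfc=("C3" if filled else "none"), mec="C3")
        if p.get("label"):
            ax.annotate(p["label"], (a * p["u"], b * p["v"]), fontsize=6,
                        xytext=(2, 2), textcoords="offset points")
    ax.set_xlabel("u (patient-left →)")
    ax.set_ylabel("v (posterior →)")
    ax.set_aspect("equal")
    ax.invert_yaxis()  # anterior up, as in an axial image viewed from feet
    if out_path is not None:
        ax.figure.savefig(out_path, bbox_inches="tight", dpi=150)
    return ax
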