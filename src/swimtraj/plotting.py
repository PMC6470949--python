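"""Basic trajectory plots (requires the optional matplotlib extra)."""

from __future__ import annotations

import numpy as np


def plot_class_means(class_means, fit=None, data=None, ax=None):
    """Plot observed weighted class-mean TTL trajectories.

    ``class_means`` is the tidy frame from
    :func:`swimtraj.lcmm.weighted_class_means`.  When ``fit`` and
    ``data`` are given, the fitted spline mean curves are overlaid as
    dashed lines.  The x axis runs from many weeks before the best
    performance (left) down to the final week (right).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4.5))
    for g, grp in class_means.groupby("class"):
        grp = grp.sort_values("week_before_bp", ascending=False)
        line, = ax.plot(grp["week_before_bp"], grp["mean"],
                        marker="o", ms=3, label=f"class {g}")
        if fit is not None and data is not None:
            t = np.asarray(grp["week_before_bp"], dtype=float)
            ax.plot(t, fit.class_curve(int(g), t, data),
                    ls="--", color=line.get_color(), alpha=0.7)
    ax.set_xlabel("weeks before best performance")
    ax.set_ylabel("TTL (%)")
    ax.invert_xaxis()
    ax.legend()
    return ax
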