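"""Hypnogram plotting."""

from __future__ import annotations

from . import STAGES

# conventional vertical ordering: deep sleep at the bottom, wake on top
_Y_ORDER = ("N3", "N2", "N1", "R", "W")


def plot_hypnogram(stages, ax=None, epoch_s: float = 30.0, title: str | None = None):
    """Step plot of a stage sequence over time.

    Returns the matplotlib Axes.  Creates a new figure when ``ax`` is
    None.
    """
    import matplotlib.pyplot as plt

    bad = set(stages) - set(STAGES)
    if bad:
        raise ValueError(f"non-canonical stages: {sorted(bad)}")
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2.5))
    y = [_Y_ORDER.index(s) for s in stages]
    t = [i * epoch_s / 3600.0 for i in range(len(stages))]
    ax.step(t, y, where="post", lw=0.8)
    ax.set_yticks(range(len(_Y_ORDER)))
    ax.set_yticklabels(_Y_ORDER)
    ax.set_xlabel("time since lights out (h)")
    ax.set_ylabel("stage")
    if title:
        ax.set_title(title)
    return ax
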