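"""Optional matplotlib rendering of the uncertainty outputs.

The core toolchain is headless and emits tidy CSV; these helpers render the
three standard figures from those frames.  matplotlib is imported lazily so
the rest of the package has no hard dependency on a display stack.
"""

from __future__ import annotations


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_ce_plane(frame, thresholds=(20_000.0, 30_000.0), ax=None):
    """Scatter of (dQALY, dCost) draws per scenario with willingness-to-pay
    rays through the origin."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots()
    for label, g in frame.groupby("scenario"):
        ax.scatter(g["delta_qaly"], g["delta_cost"], s=8, alpha=0.6, label=label)
    qmax = float(frame["delta_qaly"].abs().max()) * 1.1 or 1.0
    for lam in thresholds:
        ax.plot([-qmax, qmax], [-lam * qmax, lam * qmax], ls="--", lw=0.8, c="grey")
    ax.axhline(0, c="k", lw=0.5)
    ax.axvline(0, c="k", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (GBP)")
    ax.legend()
    return ax


def plot_ceac(frames, ax=None):
    """CEAC curves (one frame per scenario, as returned by uncertainty.ceac)."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots()
    for f in frames:
        ax.plot(f["lambda"], f["probability"], label=str(f["scenario"].iloc[0]))
    for lam in (20_000.0, 30_000.0):
        ax.axvline(lam, ls=":", c="grey", lw=0.8)
    ax.set_xlabel("Willingness-to-pay (GBP/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax


def plot_tornado(table, ax=None):
    """Horizontal bars (low..high ICER) per parameter, widest on top."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots()
    base = table.attrs.get("base_icer")
    t = table.iloc[::-1]
    ax.barh(t["parameter"], t["high"] - t["low"], left=t["low"], color="steelblue")
    if base is not None:
        ax.axvline(base, c="k", ls="--", lw=0.8)
    ax.set_xlabel("ICER (GBP/QALY)")
    return ax
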