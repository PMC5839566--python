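"""Accuracy summaries: manual vs automated count comparison.

The headline statistic is the mean absolute percentage error (MAPE)
over (manual, software) count pairs:

    MAPE = mean_i |software_i - manual_i| / manual_i * 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["mape", "CountComparison", "compare_counts"]


def mape(pairs) -> float:
    """Mean absolute percentage error over (manual, software) pairs."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("mape needs at least one pair")
    errs = []
    for manual, software in pairs:
        if manual <= 0:
            raise ValueError("manual counts must be positive")
        errs.append(abs(software - manual) / manual * 100.0)
    return float(np.mean(errs))


@dataclass
class CountComparison:
    pairs: list[tuple[float, float]]
    errors_pct: list[float] = field(default_factory=list)
    mape_pct: float = 0.0

    def to_dict(self) -> dict:
        return {"pairs": [list(p) for p in self.pairs],
                "errors_pct": self.errors_pct, "mape_pct": self.mape_pct}


def compare_counts(manual, software, plot_path=None) -> CountComparison:
    """Pair up manual and automated counts and summarize the error.

    Optionally writes a manual-vs-automated scatter with the identity
    line to ``plot_path``.
    """
    manual = list(manual)
    software = list(software)
    if len(manual) != len(software):
        raise ValueError("manual and software count lists differ in length")
    if not manual:
        raise ValueError("cannot compare empty count lists")
    pairs = list(zip(manual, software))
    errors = [abs(s - m) / m * 100.0 for m, s in pairs]
    comp = CountComparison(pairs=pairs, errors_pct=errors,
                           mape_pct=mape(pairs))
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(manual, software, color="tab:blue")
        lim = max(max(manual), max(software)) * 1.1
        ax.plot([0, lim], [0, lim], "k--", lw=1)
        ax.set_xlabel("manual count")
        ax.set_ylabel("automated count")
        ax.set_title(f"MAPE = {comp.mape_pct:.1f}%")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return comp
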