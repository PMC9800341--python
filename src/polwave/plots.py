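"""Basic QC figures: wave time courses and anchored metagene profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_wave_profiles(x_kb, profiles: dict, path, title: str = "") -> None:
    """One panel of metagene wave profiles, keyed by release time (min)."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for t in sorted(profiles):
        ax.plot(x_kb, profiles[t], label=f"{t:g} min")
    ax.set_xlabel("distance from TSS (kb)")
    ax.set_ylabel("coverage (rpm)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_metaplot(profile: np.ndarray, layout: dict, path, labels=("case", "control")) -> None:
    """Anchored metagene profile(s) with TSS/TES anchor lines.

    ``profile`` may be a single vector or a dict name -> vector.
    """
    fig, ax = plt.subplots(figsize=(7, 4))
    profs = profile if isinstance(profile, dict) else {labels[0]: profile}
    for name, vec in profs.items():
        ax.plot(np.arange(len(vec)), vec, label=name)
    for anchor in (layout["body"][0], layout["body"][1]):
        ax.axvline(anchor, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("bin (flanks fixed, body length-scaled)")
    ax.set_ylabel("coverage (rpm)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
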