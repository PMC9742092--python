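"""Thin optional plotting layer (requires matplotlib, extra ``plots``)."""

from __future__ import annotations

from .enrichment import EnrichmentResult, MetaProfile


def plot_metaprofile(profile: MetaProfile, path: str, title: str = "") -> None:
    """Line plot of mean signal depth versus distance from the anchors."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(profile.offsets, profile.mean_depth)
    ax.set_xlabel("distance from peak (bp)")
    ax.set_ylabel("mean depth")
    ax.set_title(title or f"metaprofile (n={profile.n_anchors})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_region_enrichment(results: list[EnrichmentResult], path: str) -> None:
    """Peak-vs-genome region fractions side by side, ratios annotated."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    regions = [r.region for r in results]
    x = range(len(regions))
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.bar([i - 0.2 for i in x], [r.peak_fraction for r in results],
           width=0.4, label="peaks")
    ax.bar([i + 0.2 for i in x], [r.genome_fraction for r in results],
           width=0.4, label="genome")
    for i, r in enumerate(results):
        ax.text(i, max(r.peak_fraction, r.genome_fraction) + 0.01,
                f"{r.enrichment_ratio:.2f}", ha="center", fontsize=7)
    ax.set_xticks(list(x))
    ax.set_xticklabels(regions, rotation=30, ha="right", fontsize=8)
    ax.set_ylabel("fraction")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
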