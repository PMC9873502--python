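"""Plots and the HTML index for a QC run.

Five figures: full per-cell gene body coverage, decile-mean coverage,
typical-cells coverage, skewed-cells coverage, and the cluster scatter
(first two decile-mean coordinates; typical in red, skewed in black).  All
artifacts are linked from a self-contained ``index.html``.  Rendering is
deterministic: fixed figure geometry, pinned PNG metadata, no timestamps.
"""

from __future__ import annotations

import html
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .errors import InputError, ParameterError
from .qc_cluster import SKEWED, TYPICAL, ClusterResult, CoverageMatrix, MeanCoverageMatrix

_TYPICAL_COLOR = "#c0392b"  # red family
_SKEWED_COLOR = "#1a1a1a"  # black family
_PNG_METADATA = {"Software": "skewc"}

_DPI = 110


def _save(fig, path: Path, fmt: str) -> Path:
    path = path.with_suffix(f".{fmt}")
    kwargs = {"dpi": _DPI}
    if fmt == "png":
        kwargs["metadata"] = _PNG_METADATA
    else:
        kwargs["metadata"] = {"CreationDate": None}
    fig.savefig(path, **kwargs)
    plt.close(fig)
    return path


def plot_gene_body_coverage(
    cov: CoverageMatrix,
    outpath: str | Path,
    subset: str = "all",
    labels: dict[str, str] | None = None,
    prjname: str = "COV",
    fmt: str = "png",
) -> Path:
    """One curve per cell over bins 1..100; caption counts ``n = subset: total``.

    ``subset`` is ``all``, ``typical`` or ``skewed``; the latter two need
    ``labels`` (cell_id -> annotation).  An empty subset is an error — an
    empty plot always means an upstream input problem and must not be
    written silently.
    """
    n_total = len(cov)
    if subset == "all":
        rows = np.arange(n_total)
        color, title_bit = "#2c6fa8", "all cells"
        caption = f"n = {n_total}"
    elif subset in (TYPICAL, SKEWED):
        if labels is None:
            raise ParameterError("labels required for subset plots")
        rows = np.array([i for i, cid in enumerate(cov.cell_ids)
                         if labels.get(cid) == subset], dtype=int)
        color = _TYPICAL_COLOR if subset == TYPICAL else _SKEWED_COLOR
        title_bit = f"{subset} cells"
        caption = f"n = {len(rows)}: {n_total}"
    else:
        raise ParameterError(f"unknown subset {subset!r}")
    if len(rows) == 0:
        raise ParameterError(f"subset {subset!r} is empty; nothing to plot")

    fig, ax = plt.subplots(figsize=(7, 4.5))
    x = np.arange(1, cov.values.shape[1] + 1)
    for i in rows:
        ax.plot(x, cov.values[i], color=color, alpha=min(1.0, 6.0 / len(rows)),
                linewidth=0.8)
    ax.set_xlabel("gene body percentile (5' -> 3')")
    ax.set_ylabel("relative coverage")
    ax.set_title(f"{prjname}: gene body coverage, {title_bit} ({caption})")
    fig.tight_layout()
    return _save(fig, Path(outpath), fmt)


def plot_mean_coverage(
    meanmat: MeanCoverageMatrix,
    outpath: str | Path,
    prjname: str = "COV",
    fmt: str = "png",
) -> Path:
    """Per-cell curves over the 10 decile means (pmean10..pmean100)."""
    if len(meanmat) == 0:
        raise ParameterError("mean coverage matrix is empty; nothing to plot")
    fig, ax = plt.subplots(figsize=(7, 4.5))
    x = np.arange(10, 101, 10)
    for row in meanmat.means:
        ax.plot(x, row, color="#2c6fa8", alpha=min(1.0, 6.0 / len(meanmat)),
                linewidth=0.8)
    ax.set_xticks(x)
    ax.set_xlabel("gene body decile (5' -> 3')")
    ax.set_ylabel("mean relative coverage")
    ax.set_title(f"{prjname}: mean gene body coverage (n = {len(meanmat)})")
    fig.tight_layout()
    return _save(fig, Path(outpath), fmt)


def plot_cluster_result(
    result: ClusterResult,
    meanmat: MeanCoverageMatrix,
    outpath: str | Path,
    prjname: str = "COV",
    fmt: str = "png",
) -> Path:
    """Scatter of the first two decile means, typical red vs skewed black."""
    if result.cell_ids != meanmat.cell_ids:
        raise ParameterError("cluster result and mean matrix are not row-aligned")
    lab = np.array(result.labels)
    fig, ax = plt.subplots(figsize=(5.5, 5))
    for name, color, marker in ((TYPICAL, _TYPICAL_COLOR, "o"),
                                (SKEWED, _SKEWED_COLOR, "o")):
        mask = lab == name
        if mask.any():
            ax.scatter(meanmat.means[mask, 0], meanmat.means[mask, 1],
                       s=22, facecolors="none", edgecolors=color, marker=marker,
                       label=f"{name} (n = {int(mask.sum())})")
    ax.set_xlabel(meanmat.columns[0])
    ax.set_ylabel(meanmat.columns[1])
    ax.set_title(f"{prjname}: trimmed clustering result\n"
                 f"k = {result.k}, alpha = {result.alpha:g}")
    ax.legend(loc="best", frameon=False)
    fig.tight_layout()
    return _save(fig, Path(outpath), fmt)


_INDEX_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; max-width: 60em; }}
figure {{ margin: 1.5em 0; }}
img {{ max-width: 100%; border: 1px solid #ccc; }}
table {{ border-collapse: collapse; }}
td, th {{ border: 1px solid #999; padding: 0.3em 0.8em; }}
</style>
</head>
<body>
<h1>{title}</h1>
<p>Gene body coverage quality control: cells with prototypical 5'&rarr;3'
coverage are <b>typical</b>; cells with distorted coverage are
<b>skewed</b> (trimmed by the clustering step).</p>
<table>
<tr><th>cells</th><th>typical</th><th>skewed</th><th>alpha</th></tr>
<tr><td>{n_total}</td><td>{n_typical}</td><td>{n_skewed}</td><td>{alpha:g}</td></tr>
</table>
<h2>Plots</h2>
{figures}
<h2>Downloads</h2>
<ul>
{downloads}
</ul>
</body>
</html>
"""


def build_index(
    outdir: str | Path,
    plots: dict[str, Path],
    tables: dict[str, Path],
    result: ClusterResult,
    prjname: str = "COV",
) -> Path:
    """Write ``index.html`` linking every plot and table in the bundle.

    Every referenced file must already exist; missing components are listed
    in one error rather than producing a dangling-link page.
    """
    outdir = Path(outdir)
    missing = [str(p) for p in list(plots.values()) + list(tables.values())
               if not Path(p).exists()]
    if missing:
        raise InputError("report components missing: " + ", ".join(missing))
    figures = "\n".join(
        f'<figure><img src="{html.escape(Path(p).name)}" alt="{html.escape(name)}">'
        f"<figcaption>{html.escape(name)}</figcaption></figure>"
        for name, p in sorted(plots.items())
    )
    downloads = "\n".join(
        f'<li><a href="{html.escape(Path(p).name)}">{html.escape(name)}</a></li>'
        for name, p in sorted(tables.items())
    )
    content = _INDEX_TEMPLATE.format(
        title=html.escape(f"{prjname} gene body coverage QC"),
        n_total=result.n_typical + result.n_skewed,
        n_typical=result.n_typical,
        n_skewed=result.n_skewed,
        alpha=result.alpha,
        figures=figures,
        downloads=downloads,
    )
    index = outdir / "index.html"
    index.write_text(content)
    return index


def generate_report(
    cov: CoverageMatrix,
    meanmat: MeanCoverageMatrix,
    result: ClusterResult,
    tables: dict[str, Path],
    outdir: str | Path,
    prjname: str = "COV",
    fmt: str = "png",
) -> Path:
    """Render the complete bundle for one clustering run; return index.html."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = dict(zip(result.cell_ids, result.labels))
    plots = {
        "gene body coverage (all cells)": plot_gene_body_coverage(
            cov, outdir / "coverage_all", "all", prjname=prjname, fmt=fmt),
        "mean gene body coverage": plot_mean_coverage(
            meanmat, outdir / "coverage_mean", prjname=prjname, fmt=fmt),
        "cluster result": plot_cluster_result(
            result, meanmat, outdir / "cluster_result", prjname=prjname, fmt=fmt),
    }
    if result.n_typical:
        plots["gene body coverage (typical cells)"] = plot_gene_body_coverage(
            cov, outdir / "coverage_typical", TYPICAL, labels, prjname, fmt)
    if result.n_skewed:
        plots["gene body coverage (skewed cells)"] = plot_gene_body_coverage(
            cov, outdir / "coverage_skewed", SKEWED, labels, prjname, fmt)
    return build_index(outdir, plots, {k: Path(v) for k, v in tables.items()},
                       result, prjname)
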