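"""Static heatmap rendering and self-contained HTML export.

Features are drawn as rows and samples as columns (the display transpose of
the internal samples x features convention).  Cell color is the colormap of
``log2(x + cutoff)`` by default, so zero counts render at the colormap
minimum.  Categorical metadata columns become color-bar tracks: one track
per requested sample field along the top, one optional feature field on the
right.  Category colors are assigned by a hash of the category string, so
the same category gets the same color across figures and runs.

Rendering is a pure view: the experiment is never reordered or mutated —
sort/cluster first, then draw.
"""

from __future__ import annotations

import hashlib
import html
import json
from dataclasses import dataclass, field as dc_field

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.colors
import matplotlib.patches
import matplotlib.pyplot as plt
import numpy as np

from .experiment import Experiment, ValidationError
from .transforms import DEFAULT_MIN_CUTOFF

#: fixed categorical palette (a colorblind-friendly 12-color cycle)
_PALETTE = [
    "#4477AA", "#EE6677", "#228833", "#CCBB44", "#66CCEE", "#AA3377",
    "#BBBBBB", "#999933", "#882255", "#44AA99", "#DDCC77", "#CC6677",
]


def category_color(category) -> str:
    """Stable category -> color mapping via an md5 hash of the string."""
    digest = hashlib.md5(str(category).encode()).digest()
    return _PALETTE[digest[0] % len(_PALETTE)]


@dataclass
class HeatmapSpec:
    sample_bar_fields: list = dc_field(default_factory=list)
    feature_bar_field: str | None = None
    color_scale: str = "log"  # log | linear
    log_cutoff: float = DEFAULT_MIN_CUTOFF
    colormap_name: str = "viridis"
    title: str = ""

    def validate(self, exp: Experiment) -> None:
        for f in self.sample_bar_fields:
            if f not in exp.sample_metadata.columns:
                raise KeyError(f"sample bar field {f!r} not in sample_metadata")
        if self.feature_bar_field and self.feature_bar_field not in exp.feature_metadata.columns:
            raise KeyError(f"feature bar field {self.feature_bar_field!r} not in feature_metadata")
        if self.color_scale not in ("log", "linear"):
            raise ValidationError(f"color_scale must be 'log' or 'linear', got {self.color_scale!r}")


def _display_matrix(exp: Experiment, spec: HeatmapSpec) -> np.ndarray:
    m = exp.dense().T  # features as rows
    if spec.color_scale == "log":
        m = np.log2(np.maximum(m, 0) + spec.log_cutoff)
    return m


def render(exp: Experiment, spec: HeatmapSpec, output: str) -> str:
    """Draw the heatmap and write it to ``output`` (.png or .svg)."""
    if exp.size == 0:
        raise ValidationError("cannot render an empty experiment")
    spec.validate(exp)
    m = _display_matrix(exp, spec)
    n_bars = len(spec.sample_bar_fields)

    plt.rcParams["svg.hashsalt"] = "abundex"
    fig_h = 6 + 0.25 * n_bars
    fig, axes = plt.subplots(
        nrows=n_bars + 1,
        ncols=2 if spec.feature_bar_field else 1,
        figsize=(8, fig_h),
        gridspec_kw={
            "height_ratios": [0.03] * n_bars + [1.0],
            "width_ratios": [1.0, 0.03] if spec.feature_bar_field else [1.0],
            "hspace": 0.05,
            "wspace": 0.02,
        },
        squeeze=False,
    )
    main_ax = axes[n_bars, 0]
    im = main_ax.imshow(m, aspect="auto", interpolation="nearest", cmap=spec.colormap_name)
    main_ax.set_xlabel("samples")
    main_ax.set_ylabel("features")
    main_ax.set_yticks([])
    main_ax.set_xticks([])

    legend_handles = []
    for i, fld in enumerate(spec.sample_bar_fields):
        ax = axes[i, 0]
        cats = exp.sample_metadata[fld].astype(str).tolist()
        colors = [category_color(f"{fld}={c}") for c in cats]
        rgb = np.array([matplotlib.colors.to_rgb(c) for c in colors])[None, :, :]
        ax.imshow(rgb, aspect="auto", interpolation="nearest")
        ax.set_yticks([0])
        ax.set_yticklabels([fld], fontsize=7)
        ax.set_xticks([])
        for cat in dict.fromkeys(cats):
            legend_handles.append(
                matplotlib.patches.Patch(color=category_color(f"{fld}={cat}"), label=f"{fld}: {cat}")
            )
        if spec.feature_bar_field:
            axes[i, 1].axis("off")

    if spec.feature_bar_field:
        ax = axes[n_bars, 1]
        cats = exp.feature_metadata[spec.feature_bar_field].astype(str).tolist()
        rgb = np.array(
            [matplotlib.colors.to_rgb(category_color(f"{spec.feature_bar_field}={c}")) for c in cats]
        )[:, None, :]
        ax.imshow(rgb, aspect="auto", interpolation="nearest")
        ax.set_xticks([])
        ax.set_yticks([])
        for cat in dict.fromkeys(cats):
            legend_handles.append(
                matplotlib.patches.Patch(
                    color=category_color(f"{spec.feature_bar_field}={cat}"),
                    label=f"{spec.feature_bar_field}: {cat}",
                )
            )

    if legend_handles:
        main_ax.legend(
            handles=legend_handles, loc="upper left", bbox_to_anchor=(1.08, 1.0),
            fontsize=6, frameon=False,
        )
    label = "log2(abundance + cutoff)" if spec.color_scale == "log" else "abundance"
    fig.colorbar(im, ax=main_ax, fraction=0.03, pad=0.12, label=label)
    if spec.title:
        fig.suptitle(spec.title)
    fig.savefig(output, dpi=100, metadata={"Date": None} if output.endswith(".svg") else None)
    plt.close(fig)
    return output


_HTML_TEMPLATE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 1em; }}
#wrap {{ display: flex; }}
canvas {{ border: 1px solid #888; image-rendering: pixelated; }}
#info {{ margin-left: 1em; font-size: 12px; max-width: 28em; }}
</style>
</head>
<body>
<h2>{title}</h2>
<div id="wrap">
<canvas id="hm" width="{width}" height="{height}"></canvas>
<div id="info">Hover for sample / feature / value.<div id="cell"></div></div>
</div>
<script id="payload" type="application/json">{payload}</script>
<script>
var D = JSON.parse(document.getElementById("payload").textContent);
var canvas = document.getElementById("hm"), ctx = canvas.getContext("2d");
var nf = D.feature_ids.length, ns = D.sample_ids.length;
var flat = [].concat.apply([], D.log_matrix);
var lo = Math.min.apply(null, flat), hi = Math.max.apply(null, flat);
var cw = canvas.width / ns, ch = canvas.height / nf;
function color(v) {{
  var t = hi > lo ? (v - lo) / (hi - lo) : 0;
  var r = Math.round(68 + t * (253 - 68)), g = Math.round(1 + t * (231 - 1)),
      b = Math.round(84 + t * (37 - 84));
  return "rgb(" + r + "," + g + "," + b + ")";
}}
for (var i = 0; i < nf; i++)
  for (var j = 0; j < ns; j++) {{
    ctx.fillStyle = color(D.log_matrix[i][j]);
    ctx.fillRect(j * cw, i * ch, Math.ceil(cw), Math.ceil(ch));
  }}
canvas.addEventListener("mousemove", function (e) {{
  var r = canvas.getBoundingClientRect();
  var j = Math.floor((e.clientX - r.left) / cw), i = Math.floor((e.clientY - r.top) / ch);
  if (i >= 0 && i < nf && j >= 0 && j < ns)
    document.getElementById("cell").textContent =
      D.sample_ids[j] + " / " + D.feature_ids[i] + " = " + D.matrix[i][j] +
      (D.annotation_summary ? " | " + (D.annotation_summary[D.feature_ids[i]] || "") : "");
}});
</script>
<!-- feature order: {feature_list} -->
</body>
</html>
"""


def export_html(
    exp: Experiment,
    spec: HeatmapSpec,
    output: str,
    annotation_store=None,
) -> str:
    """Write a single self-contained HTML heatmap view.

    The document embeds the full matrix, orderings, metadata tracks and
    (optionally) per-feature annotation summaries as JSON; it opens with no
    network access and references no external resources.  The embedded
    matrix equals the experiment's values exactly as serialized.
    """
    if exp.size == 0:
        raise ValidationError("cannot export an empty experiment")
    spec.validate(exp)
    dense = exp.dense().T  # features x samples, display orientation
    logm = _display_matrix(exp, spec)
    summary = None
    if annotation_store is not None:
        summary = {}
        for fid in exp.feature_ids:
            anns = annotation_store.feature_annotations(str(fid))
            terms = sorted({t for a in anns for t in a.terms})
            summary[str(fid)] = f"{len(anns)} annotations: {', '.join(terms[:8])}"
    payload = {
        "matrix": dense.tolist(),
        "log_matrix": logm.tolist(),
        "sample_ids": [str(s) for s in exp.sample_ids],
        "feature_ids": [str(f) for f in exp.feature_ids],
        "sample_tracks": {
            f: exp.sample_metadata[f].astype(str).tolist() for f in spec.sample_bar_fields
        },
        "feature_track": (
            exp.feature_metadata[spec.feature_bar_field].astype(str).tolist()
            if spec.feature_bar_field
            else None
        ),
        "annotation_summary": summary,
    }
    doc = _HTML_TEMPLATE.format(
        title=html.escape(spec.title or "abundance heatmap"),
        width=max(300, min(1200, 4 * len(payload["sample_ids"]))),
        height=max(300, min(1200, 4 * len(payload["feature_ids"]))),
        payload=json.dumps(payload).replace("</", "<\\/"),
        feature_list=html.escape(", ".join(payload["feature_ids"][:200])),
    )
    with open(output, "w") as fh:
        fh.write(doc)
    return output
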