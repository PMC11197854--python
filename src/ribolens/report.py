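"""Self-contained interactive HTML reports.

One output file, no network fetches: charts are inline SVG, the
footprint-length slider is a few lines of vanilla JavaScript operating
on per-length series embedded in the page, and every figure's
underlying numbers are also embedded as JSON (``<script
type="application/json">`` blocks) for machine checking. The report is
a view over library results, never a recomputation with different
parameters: the JSON blocks are exactly the numbers the analysis
functions returned.

Rendering is fully deterministic given the inputs; with the default
fixed-metadata mode no timestamps or environment details enter the
file, so two renders from identical inputs are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from ribolens.compare import gene_counts, scatter_pairs, spearman_matrix
from ribolens.ingest import LengthRange
from ribolens.qc import (
    OffsetTable,
    apply_offsets,
    detect_psite_offsets,
    frame_distribution,
    length_distribution,
    metagene,
    region_counts,
    transcript_coverage,
)
from ribolens.ribostore import OccupancyStore, read_store

__all__ = ["ReportSpec", "render_report"]


@dataclass
class ReportSpec:
    """Everything a report render needs; fully deterministic given these."""

    store_path: str
    experiments: list[str] = field(default_factory=list)  # empty = all
    length_range: Optional[LengthRange] = None
    offset_mode: str = "auto"  # "auto" | "none" | path to offsets TSV
    comparison: bool = False
    transcripts: list[str] = field(default_factory=list)  # coverage sections
    out_path: str = "report.html"
    fixed_metadata: bool = True
    export_json: bool = False


# ---------------------------------------------------------------- SVG helpers

_W, _H, _PAD = 640, 220, 36


def _scale(vals, lo, hi, out_lo, out_hi):
    span = hi - lo if hi > lo else 1.0
    return [out_lo + (v - lo) / span * (out_hi - out_lo) for v in vals]


def _svg_open(title: str) -> str:
    return (
        f'<svg viewBox="0 0 {_W} {_H}" role="img" aria-label="{title}" '
        f'style="max-width:{_W}px;width:100%;background:#fbfbfd">'
    )


def _fmt(v: float) -> str:
    return f"{v:.2f}".rstrip("0").rstrip(".")


def _svg_bars(labels, values, title, color="#3a6ea5") -> str:
    vmax = max(max(values), 1e-12)
    n = len(values)
    inner_w = _W - 2 * _PAD
    bw = inner_w / max(n, 1)
    parts = [_svg_open(title)]
    for i, (lab, v) in enumerate(zip(labels, values)):
        h = (v / vmax) * (_H - 2 * _PAD)
        x = _PAD + i * bw
        y = _H - _PAD - h
        parts.append(
            f'<rect x="{x:.1f}" y="{y:.1f}" width="{max(bw - 2, 1):.1f}" height="{h:.1f}" '
            f'fill="{color}"><title>{lab}: {_fmt(v)}</title></rect>'
        )
        if n <= 24 or i % max(n // 12, 1) == 0:
            parts.append(
                f'<text x="{x + bw / 2:.1f}" y="{_H - _PAD + 14}" font-size="10" '
                f'text-anchor="middle">{lab}</text>'
            )
    parts.append(f'<text x="{_PAD}" y="16" font-size="12" font-weight="bold">{title}</text>')
    parts.append("</svg>")
    return "".join(parts)


def _svg_line(xs, ys, title, elem_id=None, color="#b3403a") -> str:
    vmax = max(max(ys), 1e-12)
    px = _scale(xs, min(xs), max(xs), _PAD, _W - _PAD)
    py = _scale(ys, 0, vmax, _H - _PAD, _PAD)
    pts = " ".join(f"{x:.1f},{y:.1f}" for x, y in zip(px, py))
    pid = f' id="{elem_id}"' if elem_id else ""
    zero_x = _scale([0], min(xs), max(xs), _PAD, _W - _PAD)[0]
    return (
        _svg_open(title)
        + f'<line x1="{zero_x:.1f}" y1="{_PAD}" x2="{zero_x:.1f}" y2="{_H - _PAD}" '
        'stroke="#999" stroke-dasharray="3,3"/>'
        + f'<polyline{pid} points="{pts}" fill="none" stroke="{color}" stroke-width="1.5"/>'
        + f'<text x="{_PAD}" y="16" font-size="12" font-weight="bold">{title}</text>'
        + f'<text x="{zero_x:.1f}" y="{_H - _PAD + 14}" font-size="10" text-anchor="middle">0</text>'
        + "</svg>"
    )


def _svg_heatmap(names, matrix, title) -> str:
    n = len(names)
    size = min((_H - 2 * _PAD) / max(n, 1), 40)
    parts = [_svg_open(title)]
    x0, y0 = _PAD + 60, _PAD
    for i in range(n):
        for j in range(n):
            v = matrix[i][j]
            if v is None or (isinstance(v, float) and np.isnan(v)):
                fill, label = "#ddd", "undefined"
            else:
                t = (v + 1) / 2  # -1..1 -> 0..1
                r = int(255 * (1 - t))
                b = int(255 * t)
                fill, label = f"rgb({r},{80},{b})", f"{v:.3f}"
            parts.append(
                f'<rect x="{x0 + j * size:.1f}" y="{y0 + i * size:.1f}" width="{size:.1f}" '
                f'height="{size:.1f}" fill="{fill}" stroke="#fff">'
                f"<title>{names[i]} vs {names[j]}: {label}</title></rect>"
            )
        parts.append(
            f'<text x="{x0 - 6}" y="{y0 + i * size + size / 2:.1f}" font-size="10" '
            f'text-anchor="end">{names[i]}</text>'
        )
    parts.append(f'<text x="{_PAD}" y="16" font-size="12" font-weight="bold">{title}</text>')
    parts.append("</svg>")
    return "".join(parts)


def _svg_scatter(xs, ys, title) -> str:
    lo = min(min(xs), min(ys))
    hi = max(max(xs), max(ys), lo + 1e-9)
    px = _scale(xs, lo, hi, _PAD, _W - _PAD)
    py = _scale(ys, lo, hi, _H - _PAD, _PAD)
    parts = [_svg_open(title)]
    parts.append(
        f'<line x1="{_PAD}" y1="{_H - _PAD}" x2="{_W - _PAD}" y2="{_PAD}" '
        'stroke="#bbb" stroke-dasharray="3,3"/>'
    )
    for x, y in zip(px, py):
        parts.append(f'<circle cx="{x:.1f}" cy="{y:.1f}" r="2.2" fill="#3a6ea5" fill-opacity="0.6"/>')
    parts.append(f'<text x="{_PAD}" y="16" font-size="12" font-weight="bold">{title}</text>')
    parts.append("</svg>")
    return "".join(parts)


def _json_block(block_id: str, payload) -> str:
    text = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return f'<script type="application/json" id="{block_id}">{text}</script>'


_SLIDER_JS = """
function aggMetagene(expId, site) {
  var data = JSON.parse(document.getElementById('data-metagene-' + site + '-' + expId).textContent);
  var lo = parseInt(document.getElementById('slider-lo-' + expId).value);
  var hi = parseInt(document.getElementById('slider-hi-' + expId).value);
  if (lo > hi) { var t = lo; lo = hi; hi = t; }
  document.getElementById('slider-label-' + expId).textContent = lo + '-' + hi;
  var rows = data.per_length, positions = data.positions;
  var sum = new Array(positions.length).fill(0);
  for (var L = lo; L <= hi; L++) {
    var row = rows[String(L)];
    if (!row) continue;
    for (var i = 0; i < row.length; i++) sum[i] += row[i];
  }
  var W = 640, H = 220, PAD = 36;
  var vmax = Math.max.apply(null, sum.concat([1e-12]));
  var xmin = positions[0], xmax = positions[positions.length - 1];
  var pts = positions.map(function (p, i) {
    var x = PAD + (p - xmin) / (xmax - xmin) * (W - 2 * PAD);
    var y = (H - PAD) - sum[i] / vmax * (H - 2 * PAD);
    return x.toFixed(1) + ',' + y.toFixed(1);
  }).join(' ');
  document.getElementById('line-' + site + '-' + expId).setAttribute('points', pts);
}
function onSlider(expId) { aggMetagene(expId, 'start'); aggMetagene(expId, 'stop'); }
"""


# ---------------------------------------------------------------- rendering


def _resolve_offsets(store: OccupancyStore, exp: str, spec: ReportSpec) -> tuple[OffsetTable, str]:
    rng = spec.length_range or store.length_range(exp)
    if spec.offset_mode == "auto":
        return detect_psite_offsets(store, exp), "auto-detected"
    if spec.offset_mode == "none":
        return OffsetTable.from_dict({L: 0 for L in rng.lengths}), "none (raw 5' ends)"
    table = OffsetTable.from_tsv(spec.offset_mode)
    for L in rng.lengths:
        if L not in table:
            raise ValueError(f"offset TSV {spec.offset_mode} has no entry for length {L}")
    return table, f"manual ({spec.offset_mode})"


def render_report(spec: ReportSpec) -> Path:
    """Render the report described by ``spec``; returns the output path.

    All selections are validated before any file is written. Sections
    per experiment: length distribution, start/stop metagene, region
    counts, P-site offsets, frame distribution; plus optional
    per-transcript coverage and, with ``comparison=True`` (needs >= 2
    experiments), the Spearman heatmap and pairwise scatters.
    """
    store = read_store(spec.store_path)
    try:
        return _render(store, spec)
    finally:
        store.close()


def _render(store: OccupancyStore, spec: ReportSpec) -> Path:
    names = spec.experiments or store.experiment_names
    available = store.experiment_names
    for name in names:
        if name not in available:
            raise ValueError(f"no experiment {name!r}; available: {', '.join(available)}")
    if spec.comparison and len(names) < 2:
        raise ValueError("need >=2 experiments for a comparison section")
    ref = store.reference
    for tid in spec.transcripts:
        if tid not in ref:
            raise ValueError(f"unknown transcript {tid!r}")

    body: list[str] = []
    json_blocks: list[str] = []
    exported: dict[str, object] = {}

    for idx, exp in enumerate(names):
        exp_id = f"e{idx}"
        stored_rng = store.length_range(exp)
        rng = spec.length_range or stored_rng
        body.append(f'<h2>Experiment: {exp}</h2>')
        stats = store.stats(exp)
        body.append(
            f"<p>{stats.accepted:,} mapped and filtered reads; lengths "
            f"{rng.min_len}&ndash;{rng.max_len} nt of stored {stored_rng.min_len}&ndash;"
            f"{stored_rng.max_len}.</p>"
        )

        # 1. length distribution
        ld = length_distribution(store, exp, rng)
        payload = {
            "lengths": [int(x) for x in ld.index],
            "counts": [int(x) for x in ld["count"]],
            "fractions": [float(x) for x in ld["fraction"]],
        }
        exported[f"{exp}/length_distribution"] = payload
        json_blocks.append(_json_block(f"data-lengths-{exp_id}", payload))
        body.append('<section class="lengths">')
        body.append(_svg_bars(payload["lengths"], payload["counts"], "Footprint length distribution"))
        body.append("</section>")

        # 2. start/stop metagene with length slider
        body.append('<section class="metagene">')
        body.append(
            f'<p>Footprint lengths <span id="slider-label-{exp_id}">{rng.min_len}-{rng.max_len}</span> '
            f'<input type="range" id="slider-lo-{exp_id}" min="{rng.min_len}" max="{rng.max_len}" '
            f'value="{rng.min_len}" oninput="onSlider(\'{exp_id}\')"> '
            f'<input type="range" id="slider-hi-{exp_id}" min="{rng.min_len}" max="{rng.max_len}" '
            f'value="{rng.max_len}" oninput="onSlider(\'{exp_id}\')"></p>'
        )
        for site in ("start", "stop"):
            prof = metagene(store, exp, site=site, length_range=rng)
            matrix = store.metagene_matrix(exp, site)
            per_length = {
                str(L): [int(v) for v in matrix[stored_rng.index(L)]] for L in rng.lengths
            }
            payload = {
                "positions": [int(p) for p in prof.positions],
                "values": [int(v) for v in prof.values],
                "per_length": per_length,
            }
            exported[f"{exp}/metagene_{site}"] = {
                "positions": payload["positions"],
                "values": payload["values"],
            }
            json_blocks.append(_json_block(f"data-metagene-{site}-{exp_id}", payload))
            body.append(
                _svg_line(
                    list(prof.positions),
                    list(prof.values),
                    f"Metagene around {site} codon",
                    elem_id=f"line-{site}-{exp_id}",
                )
            )
        body.append("</section>")

        # 3. region counts
        rc = region_counts(store, exp, rng)
        payload = {
            "regions": list(rc.index),
            "counts": [int(x) for x in rc["count"]],
            "percents": [float(x) for x in rc["percent"]],
        }
        exported[f"{exp}/region_counts"] = payload
        json_blocks.append(_json_block(f"data-regions-{exp_id}", payload))
        body.append('<section class="regions">')
        body.append(_svg_bars(payload["regions"], payload["counts"], "Footprints per region", "#4a8f5d"))
        body.append("</section>")

        # 4. offsets table
        offsets, mode_label = _resolve_offsets(store, exp, spec)
        frame = offsets.to_frame()
        payload = {
            "mode": mode_label,
            "lengths": [int(x) for x in frame["length"]],
            "offsets": [int(x) for x in frame["offset"]],
            "confident": [bool(x) for x in frame["confident"]],
            "support": [int(x) for x in frame["support"]],
        }
        exported[f"{exp}/psite_offsets"] = payload
        json_blocks.append(_json_block(f"data-offsets-{exp_id}", payload))
        body.append('<section class="offsets">')
        body.append(f"<h3>P-site offsets ({mode_label})</h3><table><tr><th>length</th><th>offset</th>"
                    "<th>confident</th><th>support</th></tr>")
        for _, row in frame.iterrows():
            body.append(
                f"<tr><td>{row['length']}</td><td>{row['offset']}</td>"
                f"<td>{'yes' if row['confident'] else 'no'}</td><td>{row['support']}</td></tr>"
            )
        body.append("</table></section>")

        # 5. frame distribution (needs coverage)
        body.append('<section class="frames">')
        if store.has_coverage(exp):
            psite = apply_offsets(store, exp, offsets=offsets, length_range=rng)
            frac = frame_distribution(psite, ref)
            payload = {"frames": [0, 1, 2], "fractions": [float(x) for x in frac],
                       "clipped": int(psite.clipped)}
            exported[f"{exp}/frame_distribution"] = payload
            json_blocks.append(_json_block(f"data-frames-{exp_id}", payload))
            body.append(_svg_bars(["frame 0", "frame 1", "frame 2"], list(frac),
                                  "Triplet periodicity (P-site corrected)", "#8f4a8a"))
        else:
            body.append("<p>Frame distribution unavailable: store built without coverage.</p>")
        body.append("</section>")

        # optional per-transcript coverage
        for tid in spec.transcripts:
            vec, seq = transcript_coverage(
                store, exp, transcript_id=tid, length_range=rng,
                offsets=None if spec.offset_mode == "none" else offsets,
            )
            payload = {"transcript": tid, "coverage": [int(v) for v in vec],
                       "sequence": seq}
            exported[f"{exp}/coverage/{tid}"] = payload
            json_blocks.append(_json_block(f"data-cov-{exp_id}-{tid}", payload))
            body.append('<section class="coverage">')
            body.append(_svg_bars(list(range(len(vec))), [int(v) for v in vec],
                                  f"Coverage: {tid}", "#7a6ea5"))
            body.append("</section>")

    # comparison
    if spec.comparison:
        rng = spec.length_range
        gm = gene_counts(store, names, rng)
        cm = spearman_matrix(gm)
        mat = [
            [None if np.isnan(v) else float(v) for v in cm.rho.loc[a]] for a in cm.experiments
        ]
        payload = {"experiments": cm.experiments, "rho": mat,
                   "length_range": [gm.length_range.min_len, gm.length_range.max_len]}
        exported["comparison/spearman"] = payload
        json_blocks.append(_json_block("data-spearman", payload))
        body.append("<h2>Cross-experiment comparison</h2>")
        body.append('<section class="comparison">')
        body.append(_svg_heatmap(cm.experiments, mat, "Spearman correlation of CDS gene counts"))
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                pairs, rho = scatter_pairs(gm, a, b)
                payload = {
                    "exp_a": a, "exp_b": b, "rho": None if np.isnan(rho) else float(rho),
                    "x": [float(v) for v in pairs[a]],
                    "y": [float(v) for v in pairs[b]],
                    "transcripts": list(pairs.index),
                }
                exported[f"comparison/scatter/{a}__{b}"] = payload
                json_blocks.append(_json_block(f"data-scatter-{a}-{b}", payload))
                rho_txt = "undefined" if np.isnan(rho) else f"{rho:.4f}"
                body.append(_svg_scatter(payload["x"], payload["y"],
                                         f"log10 gene counts: {a} vs {b} (rho={rho_txt})"))
        body.append("</section>")

    meta = "" if spec.fixed_metadata else f"<p>store: {spec.store_path}</p>"
    html = (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        "<title>ribolens report</title>"
        "<style>body{font-family:sans-serif;max-width:720px;margin:2em auto;padding:0 1em}"
        "table{border-collapse:collapse}td,th{border:1px solid #ccc;padding:2px 8px;"
        "font-size:13px}</style>"
        f"<script>{_SLIDER_JS}</script>"
        "</head><body><h1>ribolens report</h1>"
        + meta
        + "".join(body)
        + "".join(json_blocks)
        + "</body></html>\n"
    )
    out = Path(spec.out_path)
    out.write_text(html)
    if spec.export_json:
        side = out.with_suffix(".json")
        side.write_text(json.dumps(exported, sort_keys=True, indent=1))
    return out
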