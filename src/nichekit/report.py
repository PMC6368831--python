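"""Run report: per-stage tallies, selected models, and configuration.

Renders a markdown body plus a self-contained HTML wrapper from the files a
run leaves in the project directory.  Missing inputs produce an explicit
gap in the report rather than an error, and re-rendering without
recomputation is byte-identical (no timestamps in the body).
"""

from __future__ import annotations

import base64
from pathlib import Path

import pandas as pd

__all__ = ["render_report"]

_HTML_SHELL = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>nichekit run report</title>
<style>
body {{ font-family: sans-serif; max-width: 60em; margin: 2em auto; }}
table {{ border-collapse: collapse; }}
td, th {{ border: 1px solid #999; padding: 0.3em 0.6em; }}
pre {{ background: #f4f4f4; padding: 0.8em; }}
</style></head><body>
{body}
</body></html>
"""


def _md_table(df: pd.DataFrame, max_rows: int = 50) -> str:
    df = df.head(max_rows)
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |", "|" + "---|" * len(cols)]
    for _, row in df.iterrows():
        cells = [
            f"{v:.4g}" if isinstance(v, float) else str(v) for v in row.tolist()
        ]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)


def render_report(run_dir, out_name: str = "run_report") -> tuple[Path, Path]:
    """Build <run_dir>/<out_name>.md and .html from run outputs on disk."""
    run_dir = Path(run_dir)
    parts = ["# nichekit run report", ""]
    gaps = []

    results_csv = run_dir / "calibration_results.csv"
    if results_csv.exists():
        table = pd.read_csv(results_csv)
        n = len(table)
        n_sig = int(table["significant"].sum())
        n_low = int(table["low_omission"].sum())
        n_sel = int(table["selected"].sum())
        parts += [
            "## Candidate-model evaluation",
            "",
            f"- candidate models evaluated: **{n}**",
            f"- statistically significant: **{n_sig}**",
            f"- meeting the omission criterion: **{n_low}**",
            f"- selected (Delta AICc): **{n_sel}**",
            "",
        ]
        summary = run_dir / "selection_summary.txt"
        if summary.exists():
            text = summary.read_text()
            if "fallback" in text:
                parts += ["**Note:** omission-stage fallback was triggered "
                          "(no significant model met omission <= E).", ""]
            parts += ["```", text.rstrip(), "```", ""]
        sel = table[table["selected"]]
        if len(sel):
            parts += ["### Selected models", "", _md_table(sel), ""]
    else:
        gaps.append("calibration_results.csv (run `evaluate` first)")

    plot = run_dir / "selection_plot.png"
    img_html = ""
    if plot.exists():
        payload = base64.b64encode(plot.read_bytes()).decode()
        img_html = (
            f'<img alt="omission vs AICc" '
            f'src="data:image/png;base64,{payload}" style="max-width:100%">'
        )
        parts += ["## Omission vs AICc", "", f"![omission vs AICc]({plot.name})", ""]
    else:
        gaps.append("selection_plot.png")

    feval = run_dir / "final_evaluation.csv"
    if feval.exists():
        parts += ["## Final-model evaluation (independent data)", "",
                  _md_table(pd.read_csv(feval)), ""]

    cfg = run_dir / "run_config.yaml"
    if cfg.exists():
        parts += ["## Configuration", "", "```yaml", cfg.read_text().rstrip(), "```", ""]
    else:
        gaps.append("run_config.yaml")

    if gaps:
        parts += ["## Missing inputs", ""] + [f"- {g}" for g in gaps] + [""]

    body_md = "\n".join(parts)
    md_path = run_dir / f"{out_name}.md"
    md_path.write_text(body_md)
    body_html = "<pre>" + body_md.replace("&", "&amp;").replace("<", "&lt;") + "</pre>"
    if img_html:
        body_html += img_html
    html_path = run_dir / f"{out_name}.html"
    html_path.write_text(_HTML_SHELL.format(body=body_html))
    return md_path, html_path
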