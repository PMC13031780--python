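"""Render a human-readable markdown summary from a results bundle directory."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import LepmemError

__all__ = ["render_report"]


def _load_json(path: Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


def render_report(in_dir: str | Path) -> str:
    """Build a markdown report mirroring the structure of the analysis."""
    d = Path(in_dir)
    if not (d / "run_meta.json").exists():
        raise LepmemError(f"{d} does not look like a results bundle (no run_meta.json)")
    meta = _load_json(d / "run_meta.json")
    lines = [
        "# Image-memory analysis report",
        "",
        f"Seed: {meta['seed']} — config hash: {meta['config_hash']}",
        "",
    ]

    if (d / "exclusion_report.json").exists():
        ex = _load_json(d / "exclusion_report.json")
        lines += [
            "## Participants",
            "",
            f"{ex['n_recruited']} recruited; {len(ex['excluded_ids'])} excluded for "
            f"failing one or more vigilance checks; {ex['n_retained']} retained.",
            "",
        ]

    for name, title in (
        ("model_rating.json", "Metamemory rating"),
        ("model_recognition.json", "Recognition"),
    ):
        if (d / name).exists():
            m = _load_json(d / name)
            stat = "z" if m["family"].startswith("binomial") else "t"
            lines += [
                f"## {title}",
                "",
                f"`{m['formula_label']}` (n = {m['n_obs']}, {m['n_groups']} participants)",
                "",
                f"Class effect (AP − nonAP): β = {m['beta']:.3f}, SE = {m['se']:.3f}, "
                f"{stat} = {m['stat']:.2f}, p = {m['p_value']:.3g}.",
                f"Random effects: intercept SD = {m['re_intercept_sd']:.3f}, "
                f"slope SD = {m['re_slope_sd']:.3f}.",
                f"Marginal R² = {100 * m['r2_marginal']:.1f}%, "
                f"conditional R² = {100 * m['r2_conditional']:.1f}%. AIC = {m['aic']:.1f}.",
                "",
            ]

    if (d / "spearman.json").exists():
        sp = _load_json(d / "spearman.json")["correlations"]
        lines += ["## Metamemory vs recognition", ""]
        for s in sp:
            lines.append(
                f"- {s['scope']}: Spearman ρ = {s['rho']:.2f}, p = {s['p_value']:.3g} "
                f"(n = {s['n']} images)"
            )
        lines.append("")

    if (d / "consistency.json").exists():
        co = _load_json(d / "consistency.json")
        lines += ["## Memorability consistency", ""]
        for scope, r in co["reliability"].items():
            lines.append(
                f"- {scope}: split-half reliability ρ = {r['rho_mean']:.2f} "
                f"(95% CI [{r['ci95'][0]:.2f}, {r['ci95'][1]:.2f}], "
                f"{r['n_iterations']} splits)"
            )
        lines += [
            "",
            f"Δρ (AP − nonAP) = {co['delta_rho']:.2f}, permutation p = {co['delta_p']:.3g}.",
            "",
        ]
        if (d / "rank_tests.csv").exists():
            rt = pd.read_csv(d / "rank_tests.csv")
            sig = (
                rt[rt["p_bonferroni"] < 0.05]
                .groupby(["scope", "comparison"])["rank"]
                .count()
            )
            total = rt.groupby(["scope", "comparison"])["rank"].count()
            lines.append("Per-rank sign-flip tests (Bonferroni-corrected, α = 0.05):")
            lines.append("")
            for key in total.index:
                lines.append(
                    f"- {key[0]} / {key[1]}: {int(sig.get(key, 0))} of {int(total[key])} "
                    f"ranks significant"
                )
            lines.append("")

    return "\n".join(lines)
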