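"""Combined analysis report: every method on one table, JSON + markdown.

The report echoes the exact configuration (including seeds) needed to
reproduce every stochastic step, alongside the input digest and per-method
results.  Rendering is plain markdown and JSON only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Any

import numpy as np

from . import __version__
from .bma import BMAConfig, BMAPosterior, PriorSpec, posterior_over_N
from .lcmcr import LCMCRConfig, posterior_summary, run_lcmcr, trace_summary
from .loglinear import chao_lower_bound, model_comparison, pairwise_analysis
from .tables import CaptureHistoryTable, ValidationError, descriptive_stats

__all__ = ["build_report", "report_to_markdown", "check_report_schema"]


def _round(x, nd=2):
    if x is None:
        return None
    x = float(x)
    return round(x, nd) if np.isfinite(x) else None


def build_report(t: CaptureHistoryTable, *, seed: int = 0,
                 prior: PriorSpec | None = None,
                 bma_config: BMAConfig | None = None,
                 lcmcr_config: LCMCRConfig | None = None,
                 level: float = 0.95,
                 methods: tuple[str, ...] = ("loglinear", "pairwise", "bma", "lcmcr"),
                 ) -> dict[str, Any]:
    """Run all requested analyses with shared defaults and collect results."""
    d = descriptive_stats(t)
    report: dict[str, Any] = {
        "tool": {"name": "multicrc", "version": __version__},
        "input": {
            "k": t.k,
            "n": t.n,
            "event_names": list(t.event_names),
            "counts": t.as_dict(),
            "n_j": list(d.n_j),
            "f_i": list(d.f_i),
            "u_j": list(d.u_j),
            "warnings": list(t.warnings),
        },
        "config": {"seed": seed, "level": level, "methods": list(methods)},
        "results": {},
    }
    res = report["results"]
    if "loglinear" in methods:
        rows = model_comparison(t, ci_level=level)
        res["loglinear"] = [
            {
                "model": r.spec.label,
                "N_hat": _round(r.fit.N_hat) if r.fit else None,
                "se": _round(r.fit.se) if r.fit else None,
                "ci": [_round(c) for c in r.fit.ci] if r.fit else None,
                "aic": _round(r.fit.aic) if r.fit else None,
                "bic": _round(r.fit.bic) if r.fit else None,
                "lower_bound": bool(r.fit.is_lower_bound) if r.fit else False,
                "error": r.error,
            }
            for r in rows
        ]
        chao = chao_lower_bound(t, ci_level=level)
        res["chao_moment_bound"] = {
            "N_hat": _round(chao.N_hat), "se": _round(chao.se),
            "ci": [_round(c) for c in chao.ci],
        }
    if "pairwise" in methods:
        res["pairwise"] = [
            {
                "pair": r.label, "n_a": r.n_a, "n_b": r.n_b, "m": r.m,
                "N_hat": _round(r.N_hat), "se": _round(r.se),
                "ci": [_round(c) for c in r.ci], "flag": r.flag,
            }
            for r in pairwise_analysis(t, ci_level=level)
        ]
    if "bma" in methods:
        if 3 <= t.k <= 5:
            post = posterior_over_N(t, prior, bma_config or BMAConfig(level=level))
            report["config"]["bma"] = {
                "prior": post.prior.kind,
                "median": post.prior.median, "q90": post.prior.q90,
                "N_max": post.prior.N_max, "delta": post.delta,
            }
            res["bma"] = {
                "mean": _round(post.mean), "median": _round(post.median),
                "ci": [_round(c) for c in post.ci], "level": post.level,
                "model_probabilities": {
                    m.label: _round(p, 4)
                    for m, p in sorted(zip(post.models, post.model_probs),
                                       key=lambda t_: -t_[1])[:5]
                },
            }
        else:
            res["bma"] = {"error": "model averaging needs 3 to 5 events"}
    if "lcmcr" in methods:
        cfg = lcmcr_config or LCMCRConfig()
        if cfg.seed is None:
            cfg = LCMCRConfig(**{**asdict(cfg), "seed": seed})
        draws = run_lcmcr(t, cfg)
        summ = posterior_summary(draws, level=level)
        diag = trace_summary(draws.N)
        report["config"]["lcmcr"] = {
            "max_classes": cfg.max_classes, "samples": cfg.samples,
            "burn_in": cfg.burn_in, "thinning": cfg.thinning,
            "shape": cfg.shape, "scale": cfg.scale, "seed": cfg.seed,
        }
        res["lcmcr"] = {
            "mean": _round(summ.mean), "median": _round(summ.median),
            "ci": [_round(c) for c in summ.ci], "level": level,
            "ess": _round(diag.ess, 1), "trend_flagged": diag.trend_flagged,
            "warnings": list(draws.warnings),
        }
    return report


def report_to_markdown(report: dict[str, Any]) -> str:
    lines = [f"# multicrc analysis report (v{report['tool']['version']})", ""]
    inp = report["input"]
    lines += [
        "## Input",
        "",
        f"- events: {inp['k']} ({', '.join(inp['event_names'])})",
        f"- distinct individuals observed: {inp['n']}",
        f"- per-event totals: {inp['n_j']}",
        f"- captured exactly i times (f_i): {inp['f_i']}",
        f"- first captured at event j (u_j): {inp['u_j']}",
        "",
    ]
    res = report["results"]
    if "loglinear" in res:
        lines += ["## Log-linear models", "",
                  "| model | N_hat | SE | CI | AIC | BIC |",
                  "|---|---|---|---|---|---|"]
        for r in res["loglinear"]:
            if r["error"]:
                lines.append(f"| {r['model']} | fit failed: {r['error']} | | | | |")
            else:
                tag = " (lower bound)" if r["lower_bound"] else ""
                lines.append(
                    f"| {r['model']}{tag} | {r['N_hat']} | {r['se']} | "
                    f"{r['ci'][0]}–{r['ci'][1]} | {r['aic']} | {r['bic']} |")
        c = res["chao_moment_bound"]
        lines += ["",
                  f"Chao moment lower bound: {c['N_hat']} "
                  f"(SE {c['se']}, CI {c['ci'][0]}–{c['ci'][1]})", ""]
    if "pairwise" in res:
        lines += ["## Pairwise (Chapman) estimates", "",
                  "| pair | n_a | n_b | overlap | N_hat | SE | CI |",
                  "|---|---|---|---|---|---|---|"]
        for r in res["pairwise"]:
            lines.append(
                f"| {r['pair']} | {r['n_a']} | {r['n_b']} | {r['m']} | "
                f"{r['N_hat']} | {r['se']} | {r['ci'][0]}–{r['ci'][1]} |")
        lines.append("")
    if "bma" in res:
        b = res["bma"]
        if "error" in b and b.get("error"):
            lines += ["## Bayesian model averaging", "", b["error"], ""]
        else:
            lines += ["## Bayesian model averaging", "",
                      f"- posterior mean {b['mean']}, median {b['median']}, "
                      f"{int(100 * b['level'])}% CI {b['ci'][0]}–{b['ci'][1]}",
                      f"- top dependence models: {b['model_probabilities']}", ""]
    if "lcmcr" in res:
        l = res["lcmcr"]
        lines += ["## Latent-class model", "",
                  f"- posterior mean {l['mean']}, median {l['median']}, "
                  f"{int(100 * l['level'])}% CI {l['ci'][0]}–{l['ci'][1]}",
                  f"- effective sample size {l['ess']}"
                  + (" — trend flagged, increase burn-in" if l["trend_flagged"] else ""),
                  ""]
    cfg = report["config"]
    lines += ["## Reproducibility", "",
              "```json", json.dumps(cfg, indent=2, default=str), "```", ""]
    return "\n".join(lines)


# -- minimal structural validation against the shipped JSON schema ----------

def check_report_schema(report: dict, schema: dict, path: str = "$") -> list[str]:
    """Check required keys and primitive types; returns a list of problems.

    Covers the subset of JSON Schema the shipped report schema uses
    (type, required, properties, items).
    """
    problems: list[str] = []
    typ = schema.get("type")
    typemap = {"object": dict, "array": list, "string": str,
               "number": (int, float), "integer": int, "boolean": bool}
    if typ and typ != "null" and not isinstance(report, typemap[typ]):
        if not (typ == "number" and isinstance(report, (int, float))):
            return [f"{path}: expected {typ}, got {type(report).__name__}"]
    if typ == "object":
        for key in schema.get("required", []):
            if key not in report:
                problems.append(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in report:
                problems += check_report_schema(report[key], sub, f"{path}.{key}")
    elif typ == "array" and "items" in schema:
        for i, item in enumerate(report):
            problems += check_report_schema(item, schema["items"], f"{path}[{i}]")
    return problems
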