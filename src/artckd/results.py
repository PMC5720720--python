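"""Shared results container for all model stages."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class FitResult:
    """Coefficients, uncertainties and ratio-scale summaries for one fit.

    ``table`` has one row per term with columns ``coef``, ``se``,
    ``robust_se``, ``ratio`` (hazard or rate ratio), ``ci_low``, ``ci_high``,
    ``p`` and ``suppressed`` (terms kept for adjustment whose ratios are not
    reported, e.g. the OTHER regimen category).  Confidence intervals use the
    robust SE when available, the model-based SE otherwise.
    """

    table: pd.DataFrame
    n_obs: int = 0
    n_events: int = 0
    loglik: float = np.nan
    converged: bool = True
    model: str = ""
    diagnostics: dict = field(default_factory=dict)

    @classmethod
    def from_estimates(cls, names, coef, se, robust_se=None, suppressed=(),
                       ratio_label="ratio", **kw):
        coef = np.asarray(coef, dtype=float)
        se = np.asarray(se, dtype=float)
        use = np.asarray(robust_se, dtype=float) if robust_se is not None else se
        with np.errstate(over="ignore"):
            tab = pd.DataFrame(
                {
                    "coef": coef,
                    "se": se,
                    "robust_se": use if robust_se is not None else np.nan,
                    "ratio": np.exp(coef),
                    "ci_low": np.exp(coef - 1.96 * use),
                    "ci_high": np.exp(coef + 1.96 * use),
                    "p": 2 * stats.norm.sf(np.abs(coef) / np.where(use > 0, use, np.inf)),
                    "suppressed": [n in set(suppressed) for n in names],
                },
                index=pd.Index(names, name="term"),
            )
        return cls(table=tab, **kw)

    def coef(self, term: str) -> float:
        return float(self.table.loc[term, "coef"])

    def ratio(self, term: str) -> float:
        return float(self.table.loc[term, "ratio"])

    def summary(self) -> str:
        shown = self.table[~self.table["suppressed"]]
        lines = [
            f"{self.model or 'model'}: {self.n_events} events / {self.n_obs} person-months"
            f"  loglik={self.loglik:.3f}  converged={self.converged}",
            f"{'term':<28}{'ratio':>8}{'95% CI':>18}{'p':>9}",
        ]
        for name, r in shown.iterrows():
            ci = f"({r.ci_low:.2f}-{r.ci_high:.2f})"
            lines.append(f"{name:<28}{r.ratio:>8.2f}{ci:>18}{r.p:>9.3g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "n_obs": int(self.n_obs),
            "n_events": int(self.n_events),
            "loglik": None if np.isnan(self.loglik) else float(self.loglik),
            "converged": bool(self.converged),
            "terms": {
                str(name): {
                    k: (None if pd.isna(v) else float(v))
                    for k, v in row.items()
                    if k != "suppressed"
                }
                | {"suppressed": bool(row["suppressed"])}
                for name, row in self.table.iterrows()
            },
            "diagnostics": _jsonable(self.diagnostics),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
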