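"""Top-k evaluation of causal-gene recovery."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = ["TopKReport", "top_k_accuracy"]

DEFAULT_K = (1, 5, 20, 50)


@dataclass
class TopKReport:
    """How often the causal gene lands within the first k ranked genes.

    Unranked cases (causal gene filtered out or absent) count toward
    ``n_cases`` but toward no k. Fractions are rounded to 0.1%.
    """

    k_values: tuple[int, ...]
    counts: dict[int, int]
    n_cases: int

    @property
    def fractions(self) -> dict[int, float]:
        if self.n_cases == 0:
            return {k: 0.0 for k in self.k_values}
        return {k: round(self.counts[k] / self.n_cases, 3) for k in self.k_values}

    def to_dict(self) -> dict:
        return {"k_values": list(self.k_values),
                "counts": {str(k): v for k, v in self.counts.items()},
                "fractions": {str(k): v for k, v in self.fractions.items()},
                "n_cases": self.n_cases}


def top_k_accuracy(causal_ranks: Sequence[Optional[int]],
                   k_values: Sequence[int] = DEFAULT_K) -> TopKReport:
    """Count cases with causal rank <= k for each k (None == unranked)."""
    ks = tuple(sorted(set(int(k) for k in k_values)))
    counts = {k: sum(1 for r in causal_ranks if r is not None and r <= k) for k in ks}
    return TopKReport(k_values=ks, counts=counts, n_cases=len(causal_ranks))
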