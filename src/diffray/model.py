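"""Model/Results base classes shared by the reconstruction modalities.

Each imaging modality exposes a model object built from data whose
``fit()`` returns a results object carrying the estimates, the optimizer
trace and a ``summary()`` table — mirroring the conventions of statistical
modelling packages.
"""

from __future__ import annotations

import numpy as np

from .solver import OptimResult

__all__ = ["InverseModel", "ReconstructionResults"]


class InverseModel:
    """Base class: a differentiable forward model bound to measured data."""

    def fit(self, **kwargs) -> "ReconstructionResults":  # pragma: no cover
        raise NotImplementedError

    def loss_closure(self):  # pragma: no cover
        """Return (closure, initial parameter dict) for the solver."""
        raise NotImplementedError


class ReconstructionResults:
    """Common results plumbing: optimizer diagnostics and summary table."""

    def __init__(self, model: InverseModel, optim_result: OptimResult):
        self.model = model
        self.optim_result = optim_result

    @property
    def loss_trace(self) -> np.ndarray:
        return self.optim_result.loss_trace

    @property
    def converged(self) -> bool:
        return self.optim_result.converged

    def _estimate_rows(self) -> list[tuple[str, str]]:
        return []

    def summary(self) -> str:
        res = self.optim_result
        rows = [
            ("Model", type(self.model).__name__),
            ("No. parameters", str(sum(np.size(v) for v in res.params.values()))),
            ("Iterations", str(res.n_iter)),
            ("Final loss", f"{res.final_loss:.6g}"),
            ("Converged", str(res.converged)),
            ("Stop reason", res.stop_reason),
        ]
        rows += self._estimate_rows()
        width = max(len(k) for k, _ in rows) + 2
        lines = [f"{type(self).__name__}",
                 "=" * 48]
        lines += [f"{k + ':':<{width}}{v}" for k, v in rows]
        lines.append("=" * 48)
        return "\n".join(lines)
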