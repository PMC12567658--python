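"""Architecture audits: exact parameter counts and 2xMAC FLOP counts.

Parameter counts enumerate every trainable scalar in the module tree (the
fixed DFL projection is not trainable and is excluded).  FLOPs are measured
by running a forward pass at the stated input size with the conv/linear
multiply-accumulate counter enabled: each MAC counts as two floating-point
operations, normalisation is treated as fused into the convolutions, and
elementwise/pooling work is not counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .functional import flop_audit
from .model import DetectorGraph
from .tensor import Tensor, no_grad


@dataclass
class ArchitectureStats:
    """Audit result for one graph."""

    total_params: int
    flops: int | None = None
    input_hw: int | None = None
    breakdown: dict = field(default_factory=dict)

    @property
    def params_m(self) -> float:
        """Millions, rounded to two decimals (reporting convention)."""
        return round(self.total_params / 1e6, 2)

    @property
    def flops_g(self) -> float | None:
        return None if self.flops is None else round(self.flops / 1e9, 1)

    def table(self) -> str:
        lines = [f"{'submodule':<12}{'params':>12}{'FLOPs':>16}"]
        for name, row in self.breakdown.items():
            fl = row.get("flops")
            lines.append(
                f"{name:<12}{row['params']:>12,}{(f'{fl:,}' if fl is not None else '-'):>16}"
            )
        fl = self.flops
        lines.append(
            f"{'total':<12}{self.total_params:>12,}{(f'{fl:,}' if fl is not None else '-'):>16}"
        )
        return "\n".join(lines)


def count_parameters(model: DetectorGraph) -> ArchitectureStats:
    """Exact trainable-parameter count with a per-submodule breakdown."""
    breakdown = {}
    for name, mod in model._modules.items():
        breakdown[name] = {"params": mod.num_params()}
    total = model.num_params()
    assert total == sum(r["params"] for r in breakdown.values()), "breakdown must conserve the total"
    return ArchitectureStats(total_params=total, breakdown=breakdown)


def count_flops(model: DetectorGraph, input_hw: int = 640, batch: int = 1) -> ArchitectureStats:
    """2xMAC FLOPs at the stated square input size (batch 1 by default)."""
    stats = count_parameters(model)
    was_training = model.training
    model.eval()
    x = Tensor(np.zeros((batch, 3, input_hw, input_hw), dtype=np.float32))
    with no_grad(), flop_audit() as audit:
        model(x)
    if was_training:
        model.train()
    total = audit.flops // batch
    # aggregate per-stage parameter rows into the backbone/neck/head groups
    # that the FLOP tags use, so the table rows are directly comparable
    merged = {"backbone": {"params": 0, "flops": 0},
              "neck": {"params": 0, "flops": 0},
              "head": {"params": 0, "flops": 0}}
    for name, row in stats.breakdown.items():
        group = name if name in ("neck", "head") else "backbone"
        merged[group]["params"] += row["params"]
    for tag, fl in audit.by_tag.items():
        merged[tag]["flops"] += fl // batch
    stats.breakdown = merged
    stats.flops = total
    stats.input_hw = input_hw
    return stats


def audit_variant(model: DetectorGraph, input_hw: int = 640) -> ArchitectureStats:
    return count_flops(model, input_hw=input_hw)
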