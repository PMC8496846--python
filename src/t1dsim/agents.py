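"""Mobile agent representation.

One lightweight class covers all six mobile agent types (autoantigen,
dendritic cell, antigen-presenting cell, naive / activated / cytotoxic
CD8+ T cell); class-specific behaviour lives in the engine rules.  Timers
are absolute clock hours at which the next event fires (-1 = unset).
"""

from __future__ import annotations

ANTIGEN = "antigen"
DC = "dc"
APC = "apc"
NAIVE_T = "naiveT"
ACTIVATED_T = "activatedT"
CTL = "ctl"

AGENT_CLASSES = (ANTIGEN, DC, APC, NAIVE_T, ACTIVATED_T, CTL)


class Agent:
    __slots__ = (
        "cls", "x", "y", "age_h", "lifespan_h",
        "migrate_at", "move_at", "egress_at", "arrive_at", "prolif_at",
        "engulfed", "bound_partners", "diff_cycles_done", "diff_at",
        "bindings", "alive",
    )

    def __init__(self, cls: str, x: int, y: int, lifespan_h: float = float("inf")):
        self.cls = cls
        self.x = x
        self.y = y
        self.age_h = 0.0
        self.lifespan_h = lifespan_h
        self.migrate_at = -1.0     # DC/APC: islet -> PLN relocation hour
        self.move_at = -1.0        # DC: next movement hour
        self.egress_at = -1.0      # activated T: PLN egress hour
        self.arrive_at = -1.0      # activated T: islet arrival hour
        self.prolif_at = -1.0      # CTL: next proliferation-cycle hour
        self.engulfed = 0          # DC: antigens engulfed so far
        self.bound_partners = 0    # APC/naive: current stable bindings
        self.diff_cycles_done = 0  # activated T: completed differentiation cycles
        self.diff_at = -1.0        # activated T: next differentiation-cycle hour
        self.bindings = None       # APC: list of [naive_agent, activate_at]
        self.alive = True

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Agent({self.cls}, pos=({self.x},{self.y}), age={self.age_h})"
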