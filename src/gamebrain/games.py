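"""Payoff engine and decision-variable schema for the 15 economic games.

The games are the behavioral battery used to measure prosociality: dictator,
trust, ultimatum, prisoner's dilemma (binary and continuous), faith, public
goods (with and without punishment), second- and third-party punishment,
preemptive strike, chicken, and stag hunt. All stakes are in Japanese yen
(JPY). Several games elicit decisions with the strategy method — a decision
for every possible opponent action — so one game contributes a grid of
decision variables.

Each decision variable carries a ``direction`` tag: ``prosocial`` (giving,
cooperating, trusting, returning), ``aggression`` (punishing, attacking,
defecting aggressively) or ``other`` (e.g. responder acceptance in the
ultimatum game, which mixes payoff-maximization and norm enforcement).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GameSpec",
    "VariableSpec",
    "GAMES",
    "compute_payoff",
    "default_variable_schema",
]

PROSOCIAL = "prosocial"
AGGRESSION = "aggression"
OTHER = "other"


@dataclass(frozen=True)
class VariableSpec:
    """One behavioral decision variable.

    ``lo``/``hi``/``step`` give the legal range and increment on the decision's
    own scale (JPY for transfers, a fraction for the trust-game return, 0/1
    for binary choices).
    """

    name: str
    game: str
    lo: float
    hi: float
    step: float
    direction: str
    binary: bool = False

    def __post_init__(self) -> None:
        if self.direction not in (PROSOCIAL, AGGRESSION, OTHER):
            raise ValueError(f"unknown direction tag {self.direction!r}")
        if self.hi < self.lo:
            raise ValueError("hi < lo")


@dataclass(frozen=True)
class GameSpec:
    name: str
    roles: tuple[str, ...]
    endowments: tuple[float, ...]
    multiplier: float
    decision_vars: tuple[VariableSpec, ...] = field(default_factory=tuple)
    conditions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")
        if any(e < 0 for e in self.endowments):
            raise ValueError("endowments must be nonnegative")


class UnknownGameError(KeyError):
    pass


class InvalidActionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Game definitions
# ---------------------------------------------------------------------------

# Preemptive strike: payoff of the struck (non-pressing) player per condition.
# Condition names encode the two victims' payoffs in hundreds of JPY; the
# printed rule table is reproduced verbatim, including the JPY 100 cell of
# condition 1010.
_PS_VICTIM = {
    # condition: (player1's payoff if player2 pressed, player2's if player1 pressed)
    "55": (500, 500),
    "1010": (1000, 100),
    "510": (500, 1000),
    "105": (1000, 500),
}
_PS_PRESSER = 1300
_PS_PEACE = 1500

_CG_MATRIX = {
    # (a1, a2) -> (pay1, pay2); action True = "proceed"
    (True, True): (0, 0),
    (True, False): (1200, 300),
    (False, True): (300, 1200),
    (False, False): (300, 300),
}

_SH_MATRIX = {
    # action True = "invest"
    (True, True): (1000, 1000),
    (True, False): (0, 500),
    (False, True): (500, 0),
    (False, False): (500, 500),
}

_DG_ENDOWMENTS = (1000, 300, 400, 600, 700, 1200, 1300)
_PDG1_ENDOWMENTS = (300, 800, 1500)


def _check_grid(value: float, lo: float, hi: float, step: float, what: str) -> None:
    if not (lo <= value <= hi):
        raise InvalidActionError(f"{what}={value} outside [{lo}, {hi}]")
    if step > 0 and abs((value - lo) / step - round((value - lo) / step)) > 1e-9:
        raise InvalidActionError(f"{what}={value} not on the JPY {step:g} grid")


GAMES: dict[str, GameSpec] = {
    "PDG-I": GameSpec("PDG-I", ("player1", "player2"), _PDG1_ENDOWMENTS, 2.0,
                      conditions=("300", "800", "1500")),
    "DG": GameSpec("DG", ("dictator", "recipient"), _DG_ENDOWMENTS, 1.0,
                   conditions=tuple(str(e) for e in _DG_ENDOWMENTS)),
    "faith": GameSpec("faith", ("recipient", "distributor"), (1000,), 3.0),
    "PGG-I": GameSpec("PGG-I", ("group",), (1000,), 3.0),
    "PDG-II": GameSpec("PDG-II", ("player1", "player2"), (1000,), 2.0,
                       conditions=("300", "800", "1500")),
    "SPPG": GameSpec("SPPG", ("player1", "player2"), (1000,), 2.0),
    "TG": GameSpec("TG", ("trustor", "trustee"), (1000,), 3.0),
    "UG": GameSpec("UG", ("proposer", "responder"), (1500,), 1.0),
    "TPPG-I": GameSpec("TPPG-I", ("distributor", "recipient", "third_party"), (1500,), 3.0),
    "TPPG-II": GameSpec("TPPG-II", ("distributor", "recipient", "third_party"), (1500, 500), 3.0),
    "preemptive_strike": GameSpec("preemptive_strike", ("player1", "player2"), (1500,), 1.0,
                                  conditions=("55", "1010", "510", "105")),
    "CG": GameSpec("CG", ("player1", "player2"), (0,), 1.0),
    "PGG-II": GameSpec("PGG-II", ("group",), (1000,), 3.0),
    "PGG-P": GameSpec("PGG-P", ("group",), (300,), 2.0),
    "stag_hunt": GameSpec("stag_hunt", ("player1", "player2"), (500,), 1.0),
}


# ---------------------------------------------------------------------------
# Payoffs
# ---------------------------------------------------------------------------

def compute_payoff(game: str, actions: dict, condition: str | None = None) -> dict[str, float]:
    """Payoffs (JPY) for one play of ``game`` given each role's decision.

    ``actions`` maps role names to decisions; see the per-game handlers for
    the expected keys. ``condition`` selects the stake variant for games that
    have one (PDG-I / DG endowment, preemptive-strike payoff condition).
    Punishment expenditures paid out of earnings elsewhere appear as negative
    payoffs.
    """
    if game not in GAMES:
        raise UnknownGameError(game)
    handler = _HANDLERS[game]
    return handler(actions, condition)


def _payoff_pdg1(actions: dict, condition: str | None) -> dict[str, float]:
    if condition is None:
        raise InvalidActionError("PDG-I requires an endowment condition (300/800/1500)")
    try:
        e = float(condition)
    except ValueError:
        raise InvalidActionError(f"bad PDG-I condition {condition!r}") from None
    if e not in _PDG1_ENDOWMENTS:
        raise InvalidActionError(f"PDG-I endowment must be one of {_PDG1_ENDOWMENTS}")
    g1, g2 = bool(actions["player1"]), bool(actions["player2"])
    return {
        "player1": (0.0 if g1 else e) + (2 * e if g2 else 0.0),
        "player2": (0.0 if g2 else e) + (2 * e if g1 else 0.0),
    }


def _payoff_dg(actions: dict, condition: str | None) -> dict[str, float]:
    e = float(condition) if condition is not None else 1000.0
    if e not in _DG_ENDOWMENTS:
        raise InvalidActionError(f"DG endowment must be one of {_DG_ENDOWMENTS}")
    a = float(actions["dictator"])
    _check_grid(a, 0, e, 100, "allocation")
    return {"dictator": e - a, "recipient": a}


def _payoff_faith(actions: dict, condition: str | None) -> dict[str, float]:
    entrusted = float(actions["recipient"])
    _check_grid(entrusted, 0, 1000, 100, "entrusted")
    d = float(actions["distributor"])
    _check_grid(d, 0, entrusted, 100, "distributed")
    return {"recipient": (1000 - entrusted) + 3 * d, "distributor": entrusted - d}


def _payoff_pgg(actions: dict, condition: str | None) -> dict[str, float]:
    contrib = {str(k): float(v) for k, v in actions.items()}
    if len(contrib) < 4:
        raise InvalidActionError("public goods game needs groups of four or more")
    for k, c in contrib.items():
        _check_grid(c, 0, 1000, 100, f"contribution[{k}]")
    pot = 3.0 * sum(contrib.values()) / len(contrib)
    return {k: 1000 - c + pot for k, c in contrib.items()}


def _payoff_pdg2(actions: dict, condition: str | None) -> dict[str, float]:
    c1, c2 = float(actions["player1"]), float(actions["player2"])
    _check_grid(c1, 0, 1000, 100, "given")
    _check_grid(c2, 0, 1000, 100, "given")
    return {"player1": 1000 - c1 + 2 * c2, "player2": 1000 - c2 + 2 * c1}


def _payoff_sppg(actions: dict, condition: str | None) -> dict[str, float]:
    # Two phases: a continuous PD, then mutual punishment (spend s, target
    # loses 2s; the spend comes out of overall earnings, shown as negative).
    out = {}
    give = {r: float(actions[r]["given"]) for r in ("player1", "player2")}
    spend = {r: float(actions[r].get("punish", 0.0)) for r in ("player1", "player2")}
    for r in ("player1", "player2"):
        _check_grid(give[r], 0, 1000, 100, "given")
        _check_grid(spend[r], 0, 1500, 100, "punish")
    for r, o in (("player1", "player2"), ("player2", "player1")):
        out[r] = 1000 - give[r] + 2 * give[o] - spend[r] - 2 * spend[o]
    return out


def _payoff_tg(actions: dict, condition: str | None) -> dict[str, float]:
    t = float(actions["trustor"])
    _check_grid(t, 0, 1000, 100, "transfer")
    r = float(actions["trustee"])
    if not (0.0 <= r <= 1.0) or abs(r * 10 - round(r * 10)) > 1e-9:
        raise InvalidActionError("trustee return must be a fraction on the 10% grid")
    pot = 3.0 * t
    return {"trustor": 1000 - t + r * pot, "trustee": (1 - r) * pot}


def _payoff_ug(actions: dict, condition: str | None) -> dict[str, float]:
    offer = float(actions["proposer"])
    _check_grid(offer, 0, 1500, 100, "offer")
    if bool(actions["responder"]):
        return {"proposer": 1500 - offer, "responder": offer}
    return {"proposer": 0.0, "responder": 0.0}


def _payoff_tppg(actions: dict, condition: str | None, *, third_endowment: float) -> dict[str, float]:
    alloc = float(actions["distributor"])
    _check_grid(alloc, 0, 1500, 100, "allocation")
    s = float(actions["third_party"])
    _check_grid(s, 0, 500, 100, "punish")
    return {
        "distributor": 1500 - alloc - 3 * s,
        "recipient": alloc,
        "third_party": third_endowment - s,
    }


def _payoff_ps(actions: dict, condition: str | None) -> dict[str, float]:
    if condition not in _PS_VICTIM:
        raise InvalidActionError("preemptive strike requires condition in 55/1010/510/105")
    p1, p2 = bool(actions["player1"]), bool(actions["player2"])
    if p1 and p2:
        raise InvalidActionError("only one player can press the button")
    v1, v2 = _PS_VICTIM[condition]
    if not p1 and not p2:
        return {"player1": _PS_PEACE, "player2": _PS_PEACE}
    if p1:
        return {"player1": _PS_PRESSER, "player2": v2}
    return {"player1": v1, "player2": _PS_PRESSER}


def _payoff_cg(actions: dict, condition: str | None) -> dict[str, float]:
    key = (bool(actions["player1"]), bool(actions["player2"]))
    p1, p2 = _CG_MATRIX[key]
    return {"player1": float(p1), "player2": float(p2)}


def _payoff_pggp(actions: dict, condition: str | None) -> dict[str, float]:
    # Punishment stage of the PGG-with-punishment: each player funds the
    # punishment system (JPY 0-300 in 10s); twice the pooled fund is deducted
    # from the lowest PGG contributor (ties broken by role-name order).
    fund = {str(k): float(v) for k, v in actions["fund"].items()}
    pgg = {str(k): float(v) for k, v in actions["pgg_contributions"].items()}
    if set(fund) != set(pgg):
        raise InvalidActionError("fund and pgg_contributions must cover the same players")
    for k, c in fund.items():
        _check_grid(c, 0, 300, 10, f"fund[{k}]")
    target = min(sorted(pgg), key=lambda k: pgg[k])
    pool = sum(fund.values())
    out = {k: -c for k, c in fund.items()}
    out[target] -= 2.0 * pool
    return out


def _payoff_sh(actions: dict, condition: str | None) -> dict[str, float]:
    key = (bool(actions["player1"]), bool(actions["player2"]))
    p1, p2 = _SH_MATRIX[key]
    return {"player1": float(p1), "player2": float(p2)}


_HANDLERS = {
    "PDG-I": _payoff_pdg1,
    "DG": _payoff_dg,
    "faith": _payoff_faith,
    "PGG-I": _payoff_pgg,
    "PDG-II": _payoff_pdg2,
    "SPPG": _payoff_sppg,
    "TG": _payoff_tg,
    "UG": _payoff_ug,
    "TPPG-I": lambda a, c: _payoff_tppg(a, c, third_endowment=0.0),
    "TPPG-II": lambda a, c: _payoff_tppg(a, c, third_endowment=500.0),
    "preemptive_strike": _payoff_ps,
    "CG": _payoff_cg,
    "PGG-II": _payoff_pgg,
    "PGG-P": _payoff_pggp,
    "stag_hunt": _payoff_sh,
}


# ---------------------------------------------------------------------------
# Decision-variable schema
# ---------------------------------------------------------------------------

def default_variable_schema(
    *,
    ug_offer_grid: tuple[int, int, int] = (0, 1500, 100),
    sppg_coop_grid: tuple[int, int, int] = (0, 1000, 100),
    tppg_alloc_grid: tuple[int, int, int] = (0, 1500, 100),
    tg_transfer_grid: tuple[int, int, int] = (100, 1000, 100),
) -> list[VariableSpec]:
    """Enumerate the behavioral decision variables, one per strategy-method cell.

    The default enumeration yields 108 variables across the 15 games. Every
    grid is configurable so alternative variable lists can be produced.
    """
    v: list[VariableSpec] = []

    def grid(lo: int, hi: int, step: int) -> range:
        return range(lo, hi + 1, step)

    # PDG-I: binary give/not in 4 situations x 3 endowments
    for situ in ("sim", "first", "second_offered", "second_notoffered"):
        for e in _PDG1_ENDOWMENTS:
            v.append(VariableSpec(f"pdg1_{situ}_{e}", "PDG-I", 0, 1, 1, PROSOCIAL, binary=True))
    # DG: allocation per endowment (first one-shot at 1000, then six repeats)
    for e in _DG_ENDOWMENTS:
        v.append(VariableSpec(f"dg_alloc_{e}", "DG", 0, e, 100, PROSOCIAL))
    # Faith game: amount entrusted by the recipient; amount distributed back
    v.append(VariableSpec("faith_entrusted", "faith", 0, 1000, 100, PROSOCIAL))
    v.append(VariableSpec("faith_distributed", "faith", 0, 1000, 100, PROSOCIAL))
    # Public goods I
    v.append(VariableSpec("pgg1_contribution", "PGG-I", 0, 1000, 100, PROSOCIAL))
    # PDG-II continuous give
    v.append(VariableSpec("pdg2_given", "PDG-II", 0, 1000, 100, PROSOCIAL))
    # SPPG: PD-phase give + punishment grid over opponent cooperation levels
    v.append(VariableSpec("sppg_pd_given", "SPPG", 0, 1000, 100, PROSOCIAL))
    for coop in grid(*sppg_coop_grid):
        v.append(VariableSpec(f"sppg_punish_c{coop}", "SPPG", 0, 1500, 100, AGGRESSION))
    # TG: trustor transfer + trustee return fraction per possible transfer
    v.append(VariableSpec("tg_transfer", "TG", 0, 1000, 100, PROSOCIAL))
    for t in grid(*tg_transfer_grid):
        v.append(VariableSpec(f"tg_return_t{t}", "TG", 0.0, 1.0, 0.1, PROSOCIAL))
    # UG: proposer offer + responder accept/reject per possible offer
    v.append(VariableSpec("ug_offer", "UG", 0, 1500, 100, PROSOCIAL))
    for o in grid(*ug_offer_grid):
        v.append(VariableSpec(f"ug_accept_o{o}", "UG", 0, 1, 1, OTHER, binary=True))
    # TPPG I/II: distributor allocation + third-party punishment grid
    for tag in ("tppg1", "tppg2"):
        game = "TPPG-I" if tag == "tppg1" else "TPPG-II"
        v.append(VariableSpec(f"{tag}_allocation", game, 0, 1500, 100, PROSOCIAL))
        for a in grid(*tppg_alloc_grid):
            v.append(VariableSpec(f"{tag}_punish_a{a}", game, 0, 500, 100, AGGRESSION))
    # Preemptive strike: press/not per condition
    for cond in ("55", "1010", "510", "105"):
        v.append(VariableSpec(f"ps_press_{cond}", "preemptive_strike", 0, 1, 1, AGGRESSION, binary=True))
    # Chicken: proceed in three simultaneous matrices + participant-first round
    for tag in ("m1", "m2", "m3", "first"):
        v.append(VariableSpec(f"cg_proceed_{tag}", "CG", 0, 1, 1, AGGRESSION, binary=True))
    # Public goods II + punishment-fund contribution
    v.append(VariableSpec("pgg2_contribution", "PGG-II", 0, 1000, 100, PROSOCIAL))
    v.append(VariableSpec("pggp_fund", "PGG-P", 0, 300, 10, AGGRESSION))
    # Stag hunt
    v.append(VariableSpec("sh_invest", "stag_hunt", 0, 1, 1, PROSOCIAL, binary=True))
    return v
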