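"""Per-channel and combined-channel RSWA summaries.

Counts are taken over valid (artefact-free REM) epochs and mini-epochs
only; percentages are relative to those valid denominators.  Bout
statistics (mean of per-event maximum amplitude and of duration) are
computed over phasic events, and over phasic plus intermediate events for
the "any" statistics; tonic stretches are excluded from the means.

Combined channels use union semantics for positivity ("bilateral" FDS is
left OR right) over the intersection of the constituent channels' valid
mini-epochs, so every counted mini-epoch is assessable on every channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import Role
from .rswa_detection import Category, ChannelScore

_EPS = 1e-9

#: The two combinations reported by default: chin any + forearm any, and
#: chin any + forearm phasic (the classic screening combination).
DEFAULT_COMBINATIONS = (
    (("mentalis", "any"), ("fds", "any")),
    (("mentalis", "any"), ("fds", "phasic")),
)

_GROUPS = {
    "fds": (Role.FDS_LEFT, Role.FDS_RIGHT),
    "ta": (Role.TA_LEFT, Role.TA_RIGHT),
}


@dataclass
class ChannelSummary:
    role: Role
    n_epochs_total: int
    n_epochs_valid: int
    n_mini_total: int
    n_mini_valid: int
    n_tonic: int
    n_phasic: int
    n_any: int
    pct_tonic: float
    pct_phasic: float
    pct_any: float
    mean_max_amplitude_phasic: float
    mean_duration_phasic: float
    mean_max_amplitude_any: float
    mean_duration_any: float

    def to_row(self) -> dict:
        d = dict(self.__dict__)
        d["role"] = self.role.value
        return d


@dataclass
class CombinedSummary:
    combination: str
    n_mini_valid: int
    n_positive: int
    pct: float
    available: bool = True

    def to_row(self) -> dict:
        return dict(self.__dict__)


class EmptyDenominatorWarning(UserWarning):
    pass


def _pct(count: int, denom: int) -> float:
    return 100.0 * count / denom if denom else float("nan")


def summarize_channel(score: ChannelScore) -> ChannelSummary:
    """Aggregate one channel's score table into counts and percentages."""
    if score.discarded or score.table is None:
        raise ValueError(f"channel {score.role.value} was not scored "
                         f"({score.reason})")
    ep, mi = score.table.epochs, score.table.minis
    n_ev = int(ep["valid"].sum())
    n_mv = int(mi["valid"].sum())
    if n_mv == 0:
        warnings.warn(EmptyDenominatorWarning(
            f"channel {score.role.value}: no valid mini-epochs"))
    n_tonic = int((ep["valid"] & ep["tonic"]).sum())
    n_phasic = int((mi["valid"] & mi["phasic"]).sum())
    n_any = int((mi["valid"] & mi["any"]).sum())

    phasic_ev = [e for e in score.events if e.category is Category.PHASIC]
    any_ev = [e for e in score.events
              if e.category in (Category.PHASIC, Category.INTERMEDIATE)]

    def _means(evs):
        if not evs:
            return float("nan"), float("nan")
        return (float(np.mean([e.max_amplitude for e in evs])),
                float(np.mean([e.duration for e in evs])))

    amp_p, dur_p = _means(phasic_ev)
    amp_a, dur_a = _means(any_ev)
    return ChannelSummary(
        role=score.role,
        n_epochs_total=len(ep), n_epochs_valid=n_ev,
        n_mini_total=len(mi), n_mini_valid=n_mv,
        n_tonic=n_tonic, n_phasic=n_phasic, n_any=n_any,
        pct_tonic=_pct(n_tonic, n_ev),
        pct_phasic=_pct(n_phasic, n_mv),
        pct_any=_pct(n_any, n_mv),
        mean_max_amplitude_phasic=amp_p, mean_duration_phasic=dur_p,
        mean_max_amplitude_any=amp_a, mean_duration_any=dur_a,
    )


def _expand(token: str) -> list[Role]:
    if token in _GROUPS:
        return list(_GROUPS[token])
    return [Role(token)]


def combine_channels(scores: dict[Role, ChannelScore],
                     combination: tuple[tuple[str, str], ...]
                     ) -> CombinedSummary:
    """Union-positivity over the intersection of valid mini-epochs.

    ``combination`` is a list of (role-or-group, category) pairs where
    category is ``"phasic"``, ``"any"`` or ``"tonic-epoch"`` is not
    supported (combinations are mini-epoch based).  Group tokens ``fds``
    and ``ta`` mean the bilateral pair.  A combination naming a discarded
    or absent channel is reported as unavailable.
    """
    name = " + ".join(f"{tok}_{cat}" for tok, cat in combination)
    role_cats: list[tuple[Role, str]] = []
    for token, cat in combination:
        if cat not in ("phasic", "any"):
            raise ValueError(f"unsupported category {cat!r} in combination")
        for role in _expand(token):
            role_cats.append((role, cat))

    for role, _ in role_cats:
        sc = scores.get(role)
        if sc is None or sc.discarded or sc.table is None:
            return CombinedSummary(combination=name, n_mini_valid=0,
                                   n_positive=0, pct=float("nan"),
                                   available=False)

    tables = {role: scores[role].table.minis for role, _ in role_cats}
    index = None
    for mi in tables.values():
        index = mi.index if index is None else index.intersection(mi.index)
    valid = np.ones(len(index), dtype=bool)
    for mi in tables.values():
        valid &= mi.loc[index, "valid"].to_numpy(dtype=bool)
    positive = np.zeros(len(index), dtype=bool)
    for role, cat in role_cats:
        positive |= tables[role].loc[index, cat].to_numpy(dtype=bool)
    n_valid = int(valid.sum())
    n_pos = int((valid & positive).sum())
    return CombinedSummary(combination=name, n_mini_valid=n_valid,
                           n_positive=n_pos, pct=_pct(n_pos, n_valid))


def summary_frames(scores: dict[Role, ChannelScore],
                   combinations=DEFAULT_COMBINATIONS
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the two output tables from all scored channels."""
    ch_rows, skipped = [], []
    for role, sc in scores.items():
        if sc.discarded:
            skipped.append(role)
            continue
        ch_rows.append(summarize_channel(sc).to_row())
    channel_df = pd.DataFrame(ch_rows)
    comb_rows = [combine_channels(scores, c).to_row() for c in combinations]
    combined_df = pd.DataFrame(comb_rows)
    return channel_df, combined_df
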