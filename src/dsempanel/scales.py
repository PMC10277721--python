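"""Weekly symptom scores from the QIDS-SR16 and ASRM questionnaires.

Three outcome series are constructed per participant-week:

* insomnia (0-9): sum of the three QIDS insomnia items (difficulty getting
  to sleep, staying asleep, early-morning waking);
* depression (0-27): the standard nine-domain QIDS total with the three
  insomnia items removed, so that insomnia and depression series never
  share items;
* (hypo)mania (0-16 by default): the ASRM total with the
  reduced-need-for-sleep item removed, again to keep the mania series free
  of sleep content (0-20 when that item is retained).

QIDS domain scoring takes the maximum within the sleep, appetite/weight and
psychomotor domains and sums the remaining single-item domains.  With the
insomnia items removed the sleep domain reduces to the hypersomnia item
alone, which preserves the familiar 0-27 frame; ``sleep_domain="drop"``
removes the sleep domain entirely (0-24) for sensitivity analyses.
"""

from __future__ import annotations

from collections.abc import Sequence

__all__ = [
    "N_QIDS_ITEMS",
    "N_ASRM_ITEMS",
    "QIDS_INSOMNIA_ITEMS",
    "QIDS_HYPERSOMNIA_ITEM",
    "ASRM_SLEEP_ITEM",
    "score_qids_insomnia",
    "score_qids_depression",
    "score_asrm",
]

N_QIDS_ITEMS = 16
N_ASRM_ITEMS = 5

# 1-based item positions on the QIDS-SR16.
QIDS_INSOMNIA_ITEMS = (1, 2, 3)  # sleep onset, sleep maintenance, early waking
QIDS_HYPERSOMNIA_ITEM = 4

# 1-based position of the "reduced need for sleep" item on the ASRM.
ASRM_SLEEP_ITEM = 3

# Single-item QIDS domains (1-based): sad mood, concentration, self-view,
# suicidality, interest, energy.
_QIDS_SINGLE_DOMAINS = (5, 10, 11, 12, 13, 14)
_QIDS_APPETITE_DOMAIN = (6, 7, 8, 9)
_QIDS_PSYCHOMOTOR_DOMAIN = (15, 16)


def _check_items(items: Sequence[int], n: int, hi: int, scale: str) -> list[int]:
    items = list(items)
    if len(items) != n:
        raise ValueError(f"{scale} requires exactly {n} item responses, got {len(items)}")
    for pos, value in enumerate(items, start=1):
        if not isinstance(value, (int,)) or isinstance(value, bool):
            try:
                as_int = int(value)
            except (TypeError, ValueError):
                raise ValueError(f"{scale} item {pos}: non-integer response {value!r}") from None
            if as_int != value:
                raise ValueError(f"{scale} item {pos}: non-integer response {value!r}")
            value = as_int
            items[pos - 1] = value
        if not 0 <= value <= hi:
            raise ValueError(f"{scale} item {pos}: response {value} outside 0-{hi}")
    return items


def score_qids_insomnia(items: Sequence[int]) -> int:
    """Insomnia score 0-9: sum of the three QIDS insomnia items."""
    items = _check_items(items, N_QIDS_ITEMS, 3, "QIDS")
    return sum(items[i - 1] for i in QIDS_INSOMNIA_ITEMS)


def score_qids_depression(items: Sequence[int], sleep_domain: str = "hypersomnia") -> int:
    """Depression score with the insomnia items removed.

    Parameters
    ----------
    items
        The 16 QIDS-SR16 item responses, each 0-3.
    sleep_domain
        ``"hypersomnia"`` (default) keeps the sleep domain as the
        hypersomnia item alone, giving a 0-27 total; ``"drop"`` removes the
        sleep domain entirely, giving a 0-24 total.
    """
    items = _check_items(items, N_QIDS_ITEMS, 3, "QIDS")
    if sleep_domain not in ("hypersomnia", "drop"):
        raise ValueError(f"sleep_domain must be 'hypersomnia' or 'drop', got {sleep_domain!r}")
    total = sum(items[i - 1] for i in _QIDS_SINGLE_DOMAINS)
    total += max(items[i - 1] for i in _QIDS_APPETITE_DOMAIN)
    total += max(items[i - 1] for i in _QIDS_PSYCHOMOTOR_DOMAIN)
    if sleep_domain == "hypersomnia":
        total += items[QIDS_HYPERSOMNIA_ITEM - 1]
    return total


def score_asrm(items: Sequence[int], include_sleep: bool = False) -> int:
    """ASRM (hypo)mania total; the reduced-need-for-sleep item is excluded
    unless ``include_sleep`` is set (analysis default excludes it, 0-16)."""
    items = _check_items(items, N_ASRM_ITEMS, 4, "ASRM")
    total = sum(items)
    if not include_sleep:
        total -= items[ASRM_SLEEP_ITEM - 1]
    return total
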