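"""DASS-42 scoring.

The Depression Anxiety Stress Scales (42-item form) assign each of the
42 items to exactly one of three subscales — depression, anxiety,
stress — with 14 items each.  Responses are coded 0-3, so each subscale
total lies in [0, 42]; higher totals indicate greater symptom load.

The standard item→subscale key ships with the package
(``data/dass42_key.csv``) and can be overridden with any mapping that
satisfies the 14/14/14 structure.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .errors import ValidationError

SUBSCALES = ("stress", "anxiety", "depression")
N_ITEMS = 42
ITEMS_PER_SUBSCALE = 14
MAX_SUBSCALE_SCORE = 42

ITEM_COLUMNS = [f"q{i:02d}" for i in range(1, N_ITEMS + 1)]


def load_subscale_key(path=None) -> pd.Series:
    """Return the item→subscale map as a Series indexed by item number.

    ``path=None`` loads the packaged standard DASS-42 key.
    """
    if path is None:
        source = resources.files("diimlm.data").joinpath("dass42_key.csv")
        with resources.as_file(source) as p:
            key = pd.read_csv(p)
    else:
        key = pd.read_csv(path)
    return _validate_key(key)


def _validate_key(key: pd.DataFrame) -> pd.Series:
    if set(key.columns) < {"item", "subscale"}:
        raise ValidationError("subscale key needs 'item' and 'subscale' columns")
    mapping = key.set_index("item")["subscale"]
    if sorted(mapping.index) != list(range(1, N_ITEMS + 1)):
        raise ValidationError("subscale key must cover items 1..42 exactly once")
    counts = mapping.value_counts()
    if set(counts.index) != set(SUBSCALES) or (counts != ITEMS_PER_SUBSCALE).any():
        raise ValidationError(
            "each of stress/anxiety/depression must have exactly 14 items; "
            f"got {counts.to_dict()}"
        )
    return mapping


def score_subscales(
    responses: pd.DataFrame, key: pd.Series | None = None, *, prorate_missing: bool = False
) -> pd.DataFrame:
    """Score item responses into the three subscale totals.

    Parameters
    ----------
    responses
        One row per participant.  Item columns may be named ``q01..q42``
        or plain integers ``1..42``; a ``participant_id`` column, if
        present, becomes the index of the result.
    key
        Item→subscale map (from :func:`load_subscale_key`); the packaged
        standard key is used when omitted.
    prorate_missing
        If True, a participant's missing items are imputed with the mean
        of their answered items on the same subscale (total rescaled to
        14 items).  Off by default: missing responses are an error.

    Returns
    -------
    DataFrame with columns ``stress``, ``anxiety``, ``depression``,
    each an integer total in [0, 42] (prorated totals may be fractional).
    """
    if key is None:
        key = load_subscale_key()
    else:
        key = _validate_key(key.rename("subscale").rename_axis("item").reset_index())

    df = responses.copy()
    index = None
    if "participant_id" in df.columns:
        index = df.pop("participant_id")

    colmap = {}
    for item in range(1, N_ITEMS + 1):
        for cand in (f"q{item:02d}", f"q{item}", item, str(item)):
            if cand in df.columns:
                colmap[item] = cand
                break
    missing_cols = [i for i in range(1, N_ITEMS + 1) if i not in colmap]
    if missing_cols:
        raise ValidationError(f"missing item columns: {missing_cols}")

    items = df[[colmap[i] for i in range(1, N_ITEMS + 1)]].astype(float)
    items.columns = range(1, N_ITEMS + 1)

    na_mask = items.isna()
    if na_mask.any().any() and not prorate_missing:
        bad = sorted(na_mask.any(axis=0).pipe(lambda s: s[s].index.tolist()))
        raise ValidationError(f"missing responses for items {bad}")

    answered = items.where(~na_mask)
    out_of_range = ((answered < 0) | (answered > 3) | (answered % 1 != 0)) & ~na_mask
    if out_of_range.any().any():
        bad = sorted(out_of_range.any(axis=0).pipe(lambda s: s[s].index.tolist()))
        raise ValidationError(f"responses outside {{0,1,2,3}} for items {bad}")

    scores = {}
    for sub in SUBSCALES:
        cols = key[key == sub].index
        block = items[cols]
        if prorate_missing:
            n_answered = block.notna().sum(axis=1)
            if (n_answered == 0).any():
                raise ValidationError(
                    f"participant answered no items on subscale '{sub}'"
                )
            scores[sub] = block.mean(axis=1) * ITEMS_PER_SUBSCALE
        else:
            scores[sub] = block.sum(axis=1)

    result = pd.DataFrame(scores, columns=list(SUBSCALES))
    if index is not None:
        result.index = pd.Index(index, name="participant_id")
    return result


def read_items(path) -> pd.DataFrame:
    """Read a ``dass_items.csv`` table (participant × 42 item columns)."""
    return pd.read_csv(path)


def write_outcomes(scores: pd.DataFrame, path) -> None:
    """Write subscale totals as ``outcomes.csv``."""
    scores.reset_index().to_csv(path, index=False)
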