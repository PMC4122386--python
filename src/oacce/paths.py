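"""Dotted-path access into nested parameter structures.

Paths address fields of :class:`~oacce.params.ModelParameters` (or any
nested pydantic model / dict / list), e.g. ``"rates.apixaban.ischemic_stroke"``
or ``"utilities.events.stroke_mild"``. Integer-looking segments index lists
and integer-keyed mappings. Used by the tornado sweep and the PSA sampler so
that every uncertain parameter has a stable, serialisable identifier.
"""

from __future__ import annotations

from typing import Any

from pydantic import BaseModel

from .errors import ConfigurationError


def _step(obj: Any, seg: str) -> Any:
    if isinstance(obj, BaseModel):
        if seg in type(obj).model_fields:
            return getattr(obj, seg)
        raise KeyError(seg)
    if isinstance(obj, dict):
        if seg in obj:
            return obj[seg]
        try:
            iseg = int(seg)
        except ValueError:
            raise KeyError(seg) from None
        if iseg in obj:
            return obj[iseg]
        raise KeyError(seg)
    if isinstance(obj, (list, tuple)):
        return obj[int(seg)]
    raise KeyError(seg)


def get_by_path(obj: Any, path: str) -> Any:
    """Return the value at a dotted *path*, raising ``ConfigurationError``
    if any segment does not resolve."""
    cur = obj
    for seg in path.split("."):
        try:
            cur = _step(cur, seg)
        except (KeyError, IndexError, ValueError):
            raise ConfigurationError(f"parameter path not resolvable: {path!r} (at {seg!r})")
    return cur


def set_in_tree(tree: Any, path: str, value: Any) -> None:
    """Set *value* at *path* inside a plain dict/list tree (as produced by
    ``ModelParameters.model_dump()``), mutating the tree in place."""
    segs = path.split(".")
    cur = tree
    for seg in segs[:-1]:
        try:
            cur = _step(cur, seg)
        except (KeyError, IndexError, ValueError):
            raise ConfigurationError(f"parameter path not resolvable: {path!r} (at {seg!r})")
    last = segs[-1]
    if isinstance(cur, dict):
        if last in cur:
            cur[last] = value
        else:
            try:
                ilast = int(last)
            except ValueError:
                raise ConfigurationError(f"parameter path not resolvable: {path!r} (at {last!r})")
            if ilast in cur:
                cur[ilast] = value
            else:
                raise ConfigurationError(f"parameter path not resolvable: {path!r} (at {last!r})")
    elif isinstance(cur, list):
        try:
            cur[int(last)] = value
        except (ValueError, IndexError):
            raise ConfigurationError(f"parameter path not resolvable: {path!r} (at {last!r})")
    else:
        raise ConfigurationError(f"parameter path not resolvable: {path!r} (at {last!r})")
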