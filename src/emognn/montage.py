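"""Electrode montages and the pairings that define asymmetry features.

Mirror (left/right homolog) pairs are derived from 10-20 extended label
conventions: a trailing odd number marks a left-hemisphere site, an even
number its right homolog, and a trailing ``z``/``Z`` the midline.
Frontal-to-posterior ("caudal") pairs cannot be recovered from names alone
and are read from a packaged resource table.

.. note::
   The packaged 23 caudal pairs follow the common convention used with
   62-channel caps in the EEG emotion-recognition literature; they are an
   editable resource, not a physical constant.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources as _ilr

__all__ = ["Montage", "derive_mirror_pairs", "load_default_montage", "load_montage_csv"]

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(\d+|[zZ])$")


def _parse_label(label: str) -> tuple[str, int | None]:
    """Split a 10-20 label into (base, suffix). suffix None means midline."""
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"cannot parse electrode label {label!r} as 10-20 extended")
    base, suffix = m.group(1), m.group(2)
    if suffix in ("z", "Z"):
        return base.upper(), None
    return base.upper(), int(suffix)


def is_midline(label: str) -> bool:
    return _parse_label(label)[1] is None


def derive_mirror_pairs(labels: list[str]) -> list[tuple[int, int]]:
    """Return (left_index, right_index) homolog pairs from label parity.

    Odd-numbered labels are left hemisphere and pair with the same base
    name carrying the next even number (F3-F4, FT7-FT8, CB1-CB2, ...).
    Midline labels are skipped. A lateral label without a homolog in
    ``labels`` raises ``ValueError`` naming the offender.
    """
    index: dict[tuple[str, int], int] = {}
    for i, lab in enumerate(labels):
        base, suffix = _parse_label(lab)
        if suffix is not None:
            index[(base, suffix)] = i

    pairs: list[tuple[int, int]] = []
    for i, lab in enumerate(labels):
        base, suffix = _parse_label(lab)
        if suffix is None or suffix % 2 == 0:
            continue
        right = index.get((base, suffix + 1))
        if right is None:
            raise ValueError(f"lateral electrode {lab!r} has no right homolog in montage")
        pairs.append((i, right))
    # evenness check: every even-suffixed label must have been consumed
    matched_right = {r for _, r in pairs}
    for i, lab in enumerate(labels):
        base, suffix = _parse_label(lab)
        if suffix is not None and suffix % 2 == 0 and i not in matched_right:
            raise ValueError(f"lateral electrode {lab!r} has no left homolog in montage")
    return pairs


@dataclass(frozen=True)
class Montage:
    """Ordered electrode labels plus the derived pairings.

    Attributes
    ----------
    labels : ordered electrode names (length E).
    midline_flags : True where the label sits on the midline.
    mirror_pairs : (left_index, right_index) homolog pairs.
    caudal_pairs : (frontal_index, posterior_index) pairs.
    """

    labels: tuple[str, ...]
    midline_flags: tuple[bool, ...] = field(default=())
    mirror_pairs: tuple[tuple[int, int], ...] = field(default=())
    caudal_pairs: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        n = len(self.labels)
        if not self.midline_flags:
            object.__setattr__(
                self, "midline_flags", tuple(is_midline(l) for l in self.labels)
            )
        seen: set[int] = set()
        for a, b in self.mirror_pairs:
            for idx in (a, b):
                if not 0 <= idx < n:
                    raise ValueError(f"mirror pair index {idx} out of range for E={n}")
                if idx in seen:
                    raise ValueError(f"index {idx} repeated in mirror_pairs")
                seen.add(idx)
            if self.midline_flags[a] or self.midline_flags[b]:
                raise ValueError("mirror pairs must not touch midline electrodes")
        for a, b in self.caudal_pairs:
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"caudal pair ({a}, {b}) out of range for E={n}")

    @property
    def n_electrodes(self) -> int:
        return len(self.labels)

    @classmethod
    def from_labels(
        cls,
        labels: list[str],
        caudal_pairs: list[tuple[int, int]] | None = None,
    ) -> "Montage":
        """Build a montage, deriving mirror pairs from the label names."""
        return cls(
            labels=tuple(labels),
            mirror_pairs=tuple(derive_mirror_pairs(list(labels))),
            caudal_pairs=tuple(caudal_pairs or ()),
        )


def load_montage_csv(path) -> Montage:
    """Load a montage from a CSV resource.

    Expected columns: ``label``, ``midline`` (0/1), ``mirror_of`` (label or
    empty) and ``caudal_partner`` (label or empty, given on the frontal
    member of each pair). Mirror pairs are re-derived from the label names
    and cross-checked against the ``mirror_of`` column; a mismatch means
    the resource is corrupted and raises ``ValueError``.
    """
    rows: list[dict[str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"label", "midline", "mirror_of", "caudal_partner"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"montage resource {path} missing columns {required}")
        rows = list(reader)
    labels = [r["label"] for r in rows]
    if len(set(labels)) != len(labels):
        raise ValueError(f"montage resource {path} has duplicate labels")
    pos = {lab: i for i, lab in enumerate(labels)}

    for r in rows:
        if bool(int(r["midline"])) != is_midline(r["label"]):
            raise ValueError(
                f"montage resource {path}: midline flag for {r['label']!r} "
                "contradicts label naming"
            )

    mirror = derive_mirror_pairs(labels)
    declared = {
        (pos[r["label"]], pos[r["mirror_of"]])
        for r in rows
        if r["mirror_of"]
        if _parse_label(r["label"])[1] is not None
        and _parse_label(r["label"])[1] % 2 == 1
    }
    if declared != set(mirror):
        raise ValueError(f"montage resource {path}: mirror_of column inconsistent with labels")

    caudal = []
    for r in rows:
        partner = r["caudal_partner"].strip()
        if partner:
            if partner not in pos:
                raise ValueError(f"montage resource {path}: unknown caudal partner {partner!r}")
            caudal.append((pos[r["label"]], pos[partner]))

    return Montage(labels=tuple(labels), mirror_pairs=tuple(mirror), caudal_pairs=tuple(caudal))


def load_default_montage() -> Montage:
    """The packaged 62-channel montage (``esi62``): 27 mirror and 23 caudal pairs."""
    with _ilr.as_file(_ilr.files("emognn.resources") / "esi62.csv") as p:
        return load_montage_csv(p)
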