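"""Semi-quantitative in situ expression scoring and marker calling.

Each gene carries an :class:`ExpressionProfile` covering four song-system
nuclei (HVC, LMAN, RA, X).  Per-nucleus cells encode an expression level on
a 0-3 scale (printed as ``o``, ``+``, ``++``, ``+++``) and a differential
direction from -2 to +2 (printed as parenthesized down/up arrows).  A gene
is a *marker* of a pathway when its direction is nonzero in at least one
member nucleus of that pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

NUCLEI = ("hvc", "lman", "ra", "x")

#: Pathway definitions: anterior forebrain pathway and direct motor pathway.
PATHWAYS = {"AFP": ("lman", "x"), "DMP": ("hvc", "ra")}

_LEVELS = {"o": 0, "+": 1, "++": 2, "+++": 3}
_ARROWS = {"↑": 1, "↑↑": 2, "↓": -1, "↓↓": -2}


class ExpressionTokenError(ValueError):
    """Raised for an expression cell token outside the scoring grammar."""


def parse_expression_cell(token: str) -> tuple[int, int]:
    """Parse one printed expression cell into ``(level, direction)``.

    Grammar: a level in ``{o, +, ++, +++}`` optionally followed by a
    parenthesized arrow group in ``{(↑), (↑↑), (↓), (↓↓)}``.

    >>> parse_expression_cell("+++ (↑↑)")
    (3, 2)
    >>> parse_expression_cell("o (↓)")
    (0, -1)
    """
    text = token.strip()
    direction = 0
    if "(" in text:
        head, _, rest = text.partition("(")
        arrows = rest.rstrip()
        if not arrows.endswith(")"):
            raise ExpressionTokenError(f"unterminated arrow group in {token!r}")
        arrows = arrows[:-1].strip()
        if arrows not in _ARROWS:
            raise ExpressionTokenError(f"unknown arrow token {arrows!r} in {token!r}")
        direction = _ARROWS[arrows]
        text = head.strip()
    if text not in _LEVELS:
        raise ExpressionTokenError(f"unknown expression token {token!r}")
    return _LEVELS[text], direction


@dataclass(frozen=True)
class ExpressionProfile:
    """Scored (or unscored) in situ outcome for one gene.

    ``status`` is ``not_determined`` (no probe tested), ``no_signal``
    (probe tested, nothing detected anywhere in brain), or ``scored``.
    ``cells`` maps nucleus name to ``(level, direction)`` and is empty
    unless ``status == "scored"``.
    """

    status: str
    cells: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in ("not_determined", "no_signal", "scored"):
            raise ValueError(f"bad expression status {self.status!r}")
        if self.status != "scored" and self.cells:
            raise ValueError("unscored profile must not carry cells")
        if self.status == "scored" and set(self.cells) != set(NUCLEI):
            raise ValueError("scored profile must cover all four nuclei")

    @classmethod
    def from_tokens(cls, tokens: dict[str, str]) -> "ExpressionProfile":
        """Build a profile from the four printed column tokens.

        ``N.D.`` in every column means not determined; ``NS`` means the
        probe was tested but gave no brain signal.  Mixing row-status
        markers with scored cells is rejected.
        """
        vals = {k: v.strip() for k, v in tokens.items()}
        if set(vals) != set(NUCLEI):
            raise ValueError(f"expected cells for {NUCLEI}, got {sorted(vals)}")
        uniq = set(vals.values())
        if uniq == {"N.D."}:
            return cls(status="not_determined")
        if uniq == {"NS"}:
            return cls(status="no_signal")
        if uniq & {"N.D.", "NS"}:
            raise ExpressionTokenError(
                f"row mixes status markers with scored cells: {vals}"
            )
        return cls(
            status="scored",
            cells={n: parse_expression_cell(vals[n]) for n in NUCLEI},
        )

    def level(self, nucleus: str) -> int:
        return self.cells[nucleus][0]

    def direction(self, nucleus: str) -> int:
        return self.cells[nucleus][1]

    @property
    def expressed_in_song_system(self) -> bool:
        """Level >= 1 in at least one nucleus (scored profiles only)."""
        return self.status == "scored" and any(
            lvl >= 1 for lvl, _ in self.cells.values()
        )


def call_markers(
    profile: ExpressionProfile, pathways: dict[str, tuple[str, ...]] = PATHWAYS
) -> dict[str, bool]:
    """Call pathway marker status for one profile.

    A gene is a marker of a pathway iff its direction is nonzero in at
    least one member nucleus.  Unscored profiles yield no calls.
    """
    if profile.status != "scored":
        return {}
    return {
        pathway: any(profile.direction(n) != 0 for n in nuclei)
        for pathway, nuclei in pathways.items()
    }


def summarize_song_system(registry) -> dict:
    """Song-system summary counts over a loaded registry.

    Returns probed / brain-expressed / song-system-expressed totals plus
    per-pathway marker counts and gene lists.  "Probed" counts genes with
    an actual in situ outcome (scored or no-signal); rows with untested
    clones or no clone at all carry ``not_determined`` status and are
    excluded.
    """
    probed = [r for r in registry if r.expression.status != "not_determined"]
    scored = [r for r in probed if r.expression.status == "scored"]
    song = [r for r in scored if r.expression.expressed_in_song_system]
    marker_lists: dict[str, list[str]] = {p: [] for p in PATHWAYS}
    nucleus_markers: dict[str, list[str]] = {n: [] for n in NUCLEI}
    for rec in scored:
        calls = call_markers(rec.expression)
        for pathway, hit in calls.items():
            if hit:
                marker_lists[pathway].append(rec.symbol)
        for n in NUCLEI:
            if rec.expression.direction(n) != 0:
                nucleus_markers[n].append(rec.symbol)
    return {
        "probed": len(probed),
        "brain_expressed": len(scored),
        "song_system_expressed": len(song),
        "afp_markers": len(marker_lists["AFP"]),
        "dmp_markers": len(marker_lists["DMP"]),
        "marker_lists": marker_lists,
        "nucleus_markers": nucleus_markers,
        "song_system_genes": [r.symbol for r in song],
    }
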