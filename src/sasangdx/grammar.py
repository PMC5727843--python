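"""Grammar for named facial feature variables evaluated on landmarks.

Feature names encode geometric operations on numbered landmark points
of a frontal (``F``) or profile (``P``) facial image:

==============  =======================================================
``FD_a_b``      euclidean distance between points a and b (``PD_a_b``
                for the profile view)
``FDH_a_b``     horizontal distance |dx|; ``FDV_a_b`` vertical |dy|
``FA_a_b``      acute angle of the line a-b against the horizontal
``FA_a_b_c``    interior angle at vertex b
``FAs/FAi/FAis`` two-point angle variants: signed / mirrored / both
``FArea_a_b_c`` triangle area (``PArea``/``PAR`` for profile)
``FArea02``     named polygon area, defined in a YAML polygon file
``PDL_a_b_c``   perpendicular distance from point a to line b-c
``FHD_a_b_c_d`` ratio FDH(a,b)/FD(c,d); likewise ``FDD`` = FD/FD,
                ``FVD`` = FDV/FD, ``FVV`` = FDV/FDV, ``FVH`` = FDV/FDH,
                and four-argument ``FDH`` = FD/FDH
==============  =======================================================

Composite expressions combine names with ``+``, ``/``, numeric
constants and parentheses, e.g. ``(FDH_18_25+FDH_118_125)/2/FDH_18_118``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import yaml

from sasangdx.geometry import (
    Point2D,
    angle_three_point,
    angle_two_point,
    point_distance,
    point_line_distance,
    polygon_area,
)


class FeatureParseError(ValueError):
    """A feature name does not belong to the grammar."""


class MissingLandmarkError(KeyError):
    """A referenced landmark id is absent from the given view."""

    def __str__(self) -> str:  # KeyError quotes its arg by default
        return self.args[0]


@dataclass(frozen=True)
class LandmarkSet:
    """Named 2-D points for the frontal and profile views of one subject."""

    subject_id: str
    frontal: Mapping[int, Point2D]
    profile: Mapping[int, Point2D]

    def __post_init__(self):
        for view in (self.frontal, self.profile):
            for pid in view:
                if not (isinstance(pid, int) and pid > 0):
                    raise ValueError(f"landmark ids must be positive integers, got {pid!r}")

    def point(self, view: str, pid: int, context: str = "") -> Point2D:
        table = self.frontal if view == "frontal" else self.profile
        try:
            return table[pid]
        except KeyError:
            raise MissingLandmarkError(
                f"landmark {pid} missing from {view} view of subject "
                f"{self.subject_id!r}" + (f" (needed by {context})" if context else "")
            ) from None


# ---------------------------------------------------------------------------
# expression tree

@dataclass(frozen=True)
class FeatureExpr:
    """Base class; concrete nodes implement evaluate/render/pixel_power."""

    def evaluate(self, lm: LandmarkSet, polygons: Optional[Mapping] = None) -> float:
        raise NotImplementedError

    def render(self) -> str:
        raise NotImplementedError

    def pixel_power(self) -> int:
        """Length dimension: 1 for distances, 2 for areas, 0 for angles,
        ratios and constants.  Power-0 features are invariant under
        uniform scaling of the landmarks."""
        raise NotImplementedError

    def point_refs(self) -> List[Tuple[str, int]]:
        return []


def _vtag(view: str) -> str:
    return "F" if view == "frontal" else "P"


@dataclass(frozen=True)
class Distance(FeatureExpr):
    view: str
    mode: str  # euclidean | horizontal | vertical
    p: int
    q: int

    def evaluate(self, lm, polygons=None):
        name = self.render()
        return point_distance(lm.point(self.view, self.p, name),
                              lm.point(self.view, self.q, name), self.mode)

    def render(self):
        suffix = {"euclidean": "D", "horizontal": "DH", "vertical": "DV"}[self.mode]
        return f"{_vtag(self.view)}{suffix}_{self.p}_{self.q}"

    def pixel_power(self):
        return 1

    def point_refs(self):
        return [(self.view, self.p), (self.view, self.q)]


@dataclass(frozen=True)
class TwoPointAngle(FeatureExpr):
    view: str
    p: int
    q: int
    signed: bool = False
    mirrored: bool = False

    def evaluate(self, lm, polygons=None):
        name = self.render()
        return angle_two_point(lm.point(self.view, self.p, name),
                               lm.point(self.view, self.q, name),
                               signed=self.signed, mirrored=self.mirrored)

    def render(self):
        flags = ("i" if self.mirrored else "") + ("s" if self.signed else "")
        return f"{_vtag(self.view)}A{flags}_{self.p}_{self.q}"

    def pixel_power(self):
        return 0

    def point_refs(self):
        return [(self.view, self.p), (self.view, self.q)]


@dataclass(frozen=True)
class ThreePointAngle(FeatureExpr):
    view: str
    a: int
    b: int
    c: int

    def evaluate(self, lm, polygons=None):
        name = self.render()
        return angle_three_point(lm.point(self.view, self.a, name),
                                 lm.point(self.view, self.b, name),
                                 lm.point(self.view, self.c, name))

    def render(self):
        return f"{_vtag(self.view)}A_{self.a}_{self.b}_{self.c}"

    def pixel_power(self):
        return 0

    def point_refs(self):
        return [(self.view, self.a), (self.view, self.b), (self.view, self.c)]


@dataclass(frozen=True)
class TriangleArea(FeatureExpr):
    view: str
    a: int
    b: int
    c: int

    def evaluate(self, lm, polygons=None):
        name = self.render()
        return polygon_area([lm.point(self.view, p, name) for p in (self.a, self.b, self.c)])

    def render(self):
        return f"{_vtag(self.view)}Area_{self.a}_{self.b}_{self.c}"

    def pixel_power(self):
        return 2

    def point_refs(self):
        return [(self.view, p) for p in (self.a, self.b, self.c)]


@dataclass(frozen=True)
class NamedArea(FeatureExpr):
    """A polygon area referenced by name; the polygon's view and ordered
    point list come from a polygon-definition mapping."""

    name: str

    def evaluate(self, lm, polygons=None):
        if not polygons or self.name not in polygons:
            raise FeatureParseError(
                f"named area {self.name!r} has no polygon definition")
        spec = polygons[self.name]
        view, pids = spec["view"], spec["points"]
        return polygon_area([lm.point(view, p, self.name) for p in pids])

    def render(self):
        return self.name

    def pixel_power(self):
        return 2


@dataclass(frozen=True)
class PointToLine(FeatureExpr):
    """Perpendicular distance from point ``p`` to the line ``a``-``b``."""

    view: str
    p: int
    a: int
    b: int

    def evaluate(self, lm, polygons=None):
        name = self.render()
        return point_line_distance(lm.point(self.view, self.p, name),
                                   lm.point(self.view, self.a, name),
                                   lm.point(self.view, self.b, name))

    def render(self):
        return f"{_vtag(self.view)}DL_{self.p}_{self.a}_{self.b}"

    def pixel_power(self):
        return 1

    def point_refs(self):
        return [(self.view, p) for p in (self.p, self.a, self.b)]


@dataclass(frozen=True)
class Const(FeatureExpr):
    value: float

    def evaluate(self, lm, polygons=None):
        return self.value

    def render(self):
        v = self.value
        return str(int(v)) if float(v).is_integer() else str(v)

    def pixel_power(self):
        return 0


@dataclass(frozen=True)
class BinOp(FeatureExpr):
    """Sum or quotient of two sub-expressions; quotients realize the
    ratio composites of the vocabulary."""

    op: str  # '+' | '/'
    left: FeatureExpr
    right: FeatureExpr

    def evaluate(self, lm, polygons=None):
        l = self.left.evaluate(lm, polygons)
        r = self.right.evaluate(lm, polygons)
        if self.op == "+":
            return l + r
        return l / r if r != 0 else float("nan")

    def render(self):
        # a 4-argument ratio shorthand renders back to its shorthand
        short = self._shorthand()
        if short is not None:
            return short
        def wrap(e: FeatureExpr) -> str:
            s = e.render()
            if isinstance(e, BinOp) and e._shorthand() is None and (
                    self.op == "/" or e.op == "/"):
                return f"({s})"
            return s
        if self.op == "+":
            return f"{self.left.render()}+{self.right.render()}"
        return f"{wrap(self.left)}/{wrap(self.right)}"

    def _shorthand(self) -> Optional[str]:
        l, r = self.left, self.right
        if (self.op == "/" and isinstance(l, Distance) and isinstance(r, Distance)
                and l.view == r.view):
            combo = {
                ("horizontal", "euclidean"): "HD",
                ("euclidean", "horizontal"): "DH",
                ("euclidean", "euclidean"): "DD",
                ("vertical", "euclidean"): "VD",
                ("vertical", "vertical"): "VV",
                ("vertical", "horizontal"): "VH",
            }.get((l.mode, r.mode))
            if combo:
                return f"{_vtag(l.view)}{combo}_{l.p}_{l.q}_{r.p}_{r.q}"
        return None

    def pixel_power(self):
        lp, rp = self.left.pixel_power(), self.right.pixel_power()
        if self.op == "+":
            if lp != rp:
                raise FeatureParseError(
                    f"cannot add quantities of unequal dimension in {self.render()!r}")
            return lp
        return lp - rp

    def point_refs(self):
        return self.left.point_refs() + self.right.point_refs()


# ---------------------------------------------------------------------------
# parsing

_TOKEN_RE = re.compile(r"\s*([A-Za-z][A-Za-z0-9_]*|\d+(?:\.\d+)?|[()+/])")
_NAMED_AREA_RE = re.compile(r"^([FP])Area(\d+)$")

_RATIO_MODES = {
    "HD": ("horizontal", "euclidean"),
    "DD": ("euclidean", "euclidean"),
    "VD": ("vertical", "euclidean"),
    "VV": ("vertical", "vertical"),
    "VH": ("vertical", "horizontal"),
    "DH": ("euclidean", "horizontal"),  # 4-argument DH shorthand
}


def _parse_atom(token: str) -> FeatureExpr:
    m = _NAMED_AREA_RE.match(token)
    if m:
        return NamedArea(token)
    parts = token.split("_")
    head, raw_args = parts[0], parts[1:]
    if not raw_args:
        raise FeatureParseError(f"unknown feature token {head!r}")
    try:
        args = [int(a) for a in raw_args]
    except ValueError:
        raise FeatureParseError(f"non-integer point id in {token!r}") from None
    if any(a <= 0 for a in args):
        raise FeatureParseError(f"point ids must be positive in {token!r}")
    if head[0] not in "FP":
        raise FeatureParseError(f"unknown view prefix in token {head!r}")
    view = "frontal" if head[0] == "F" else "profile"
    op = head[1:]
    n = len(args)

    def need(k):
        if n != k:
            raise FeatureParseError(
                f"operator {head!r} expects {k} point ids, got {n} in {token!r}")

    if op == "D":
        need(2)
        return Distance(view, "euclidean", *args)
    if op == "DH":
        if n == 2:
            return Distance(view, "horizontal", *args)
        if n == 4:
            return BinOp("/", Distance(view, "euclidean", args[0], args[1]),
                         Distance(view, "horizontal", args[2], args[3]))
        raise FeatureParseError(f"operator {head!r} expects 2 or 4 ids, got {n}")
    if op == "DV":
        need(2)
        return Distance(view, "vertical", *args)
    if op == "A":
        if n == 2:
            return TwoPointAngle(view, *args)
        if n == 3:
            return ThreePointAngle(view, *args)
        raise FeatureParseError(f"operator {head!r} expects 2 or 3 ids, got {n}")
    if op in ("As", "Ai", "Ais"):
        need(2)
        return TwoPointAngle(view, *args, signed="s" in op, mirrored="i" in op)
    if op in ("Area", "AR"):
        need(3)
        return TriangleArea(view, *args)
    if op == "DL":
        need(3)
        return PointToLine(view, *args)
    if op in _RATIO_MODES:
        need(4)
        m1, m2 = _RATIO_MODES[op]
        return BinOp("/", Distance(view, m1, args[0], args[1]),
                     Distance(view, m2, args[2], args[3]))
    raise FeatureParseError(f"unknown operator token {head!r} in {token!r}")


class _Parser:
    def __init__(self, text: str):
        self.tokens: List[str] = []
        pos = 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if not m:
                raise FeatureParseError(f"cannot tokenize {text!r} at position {pos}")
            self.tokens.append(m.group(1))
            pos = m.end()
        self.i = 0

    def peek(self) -> Optional[str]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise FeatureParseError("unexpected end of feature expression")
        self.i += 1
        return tok

    def parse(self) -> FeatureExpr:
        expr = self.sum()
        if self.peek() is not None:
            raise FeatureParseError(f"trailing token {self.peek()!r}")
        return expr

    def sum(self) -> FeatureExpr:
        node = self.quot()
        while self.peek() == "+":
            self.next()
            node = BinOp("+", node, self.quot())
        return node

    def quot(self) -> FeatureExpr:
        node = self.primary()
        while self.peek() == "/":
            self.next()
            node = BinOp("/", node, self.primary())
        return node

    def primary(self) -> FeatureExpr:
        tok = self.next()
        if tok == "(":
            node = self.sum()
            if self.next() != ")":
                raise FeatureParseError("unbalanced parentheses")
            return node
        if re.fullmatch(r"\d+(?:\.\d+)?", tok):
            return Const(float(tok))
        return _parse_atom(tok)


def parse_feature_spec(name: str) -> FeatureExpr:
    """Parse a feature name or composite expression into its tree."""
    if not name or not name.strip():
        raise FeatureParseError("empty feature name")
    return _Parser(name.strip()).parse()


# ---------------------------------------------------------------------------
# evaluation over feature lists

@dataclass
class FeatureVector:
    """Ordered feature values for one subject, with non-finite entries
    flagged (never silently dropped)."""

    names: List[str]
    values: List[float]
    nonfinite: List[str] = field(default_factory=list)

    def to_dict(self) -> Dict[str, float]:
        return dict(zip(self.names, self.values))

    def __getitem__(self, name: str) -> float:
        return self.to_dict()[name]


def evaluate_feature_set(
    landmarks: LandmarkSet,
    specs: Sequence,
    polygons: Optional[Mapping] = None,
) -> FeatureVector:
    """Evaluate a list of feature specs (names or parsed expressions) on
    one subject's landmarks, preserving order."""
    import math

    if polygons is None:
        polygons = default_polygons()
    names, values, flagged = [], [], []
    for spec in specs:
        expr = parse_feature_spec(spec) if isinstance(spec, str) else spec
        name = spec if isinstance(spec, str) else expr.render()
        v = float(expr.evaluate(landmarks, polygons))
        if not math.isfinite(v):
            flagged.append(name)
        names.append(name)
        values.append(v)
    return FeatureVector(names, values, flagged)


# ---------------------------------------------------------------------------
# shipped defaults

def load_feature_names(path) -> List[str]:
    """Read a feature-spec file: one name per line, ``#`` comments."""
    names = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                names.append(line)
    return names


def default_feature_names() -> List[str]:
    """The shipped candidate facial feature vocabulary."""
    text = resources.files("sasangdx.data").joinpath("facial_features.txt").read_text()
    return [l.split("#", 1)[0].strip() for l in text.splitlines()
            if l.split("#", 1)[0].strip()]


def default_polygons() -> Dict[str, dict]:
    """Shipped polygon definitions for the named area features."""
    text = resources.files("sasangdx.data").joinpath("face_polygons.yaml").read_text()
    return yaml.safe_load(text)


def referenced_points(specs: Iterable[str]) -> Dict[str, set]:
    """All (view -> point-id set) referenced by a list of feature names,
    including polygon points of named areas."""
    out = {"frontal": set(), "profile": set()}
    polys = default_polygons()
    for name in specs:
        expr = parse_feature_spec(name)
        for view, pid in expr.point_refs():
            out[view].add(pid)
        stack = [expr]
        while stack:
            node = stack.pop()
            if isinstance(node, NamedArea) and node.name in polys:
                spec = polys[node.name]
                out[spec["view"]].update(spec["points"])
            if isinstance(node, BinOp):
                stack.extend([node.left, node.right])
    return out
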