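"""Gene panel, screening-condition registry and factorial model matrices.

The screen crosses five soluble chondrogenic differentiation factors --
TGFB1, FGF2, DEX (dexamethasone), IGF1 and BMP2 -- in a two-level
(present / absent) full 2^5 factorial arm of 32 conditions, extended by a
TGFB/BMP isoform arm and a cell-seeding-density arm to 48 conditions in
total.  Conditions carry the canonical screen numbering

    id = 32 - (16*[TGFB1] + 8*[FGF2] + 4*[DEX] + 2*[IGF1] + 1*[BMP2])

so that condition 32 is the no-factor baseline medium (bCDM) and
condition 1 is all five factors.  The numbering is exposed through
:func:`condition_number` and can be overridden by supplying custom
weights.

The gene panel holds the measured probe universe: endogenous genes
(among them the curated "wanted" hyaline-cartilage markers and the
"unwanted" hypertrophy/bone/fat markers), housekeeping candidates for
reference-gene selection, and the spike-in positive / negative control
probes used for lane scaling and background estimation.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FACTORS",
    "NUMBERING_WEIGHTS",
    "WANTED_MARKERS",
    "UNWANTED_MARKERS",
    "HOUSEKEEPING_CANDIDATES",
    "POSITIVE_CONTROLS",
    "NEGATIVE_CONTROLS",
    "UNTREATED_ID",
    "GenePanel",
    "Condition",
    "ConditionRegistry",
    "ModelMatrix",
    "PanelSizeError",
    "DesignError",
    "build_default_panel",
    "enumerate_factorial",
    "build_condition_registry",
    "condition_number",
    "make_design_table",
    "encode_model_matrix",
    "coded_model_matrix",
]

#: Factor names in canonical numbering-weight order.
FACTORS: tuple[str, ...] = ("TGFB1", "FGF2", "DEX", "IGF1", "BMP2")

#: Weights of the canonical condition-numbering rule.
NUMBERING_WEIGHTS: dict[str, int] = {
    "TGFB1": 16, "FGF2": 8, "DEX": 4, "IGF1": 2, "BMP2": 1,
}

#: Hyaline-cartilage ECM markers ("wanted" set, slash entries expanded).
WANTED_MARKERS: tuple[str, ...] = (
    "ACAN", "BGN", "COL11A1", "COL11A2", "COL2A1",
    "COL9A1", "COL9A2", "COL9A3", "COMP", "DCN",
    "FMOD", "HAPLN1", "LUM", "MATN3",
)

#: Hypertrophy / bone / fat / fibrocartilage markers ("unwanted" set).
UNWANTED_MARKERS: tuple[str, ...] = (
    "ALPL", "COL10A1", "COL1A1", "COL1A2", "COL3A1",
    "OGN", "PPARG", "RUNX2", "SP7", "SPP1", "VCAN",
)

#: Named candidate reference genes screened for stability.
HOUSEKEEPING_CANDIDATES: tuple[str, ...] = (
    "ACTB", "B2M", "GAPDH", "GUSB", "HPRT1",
    "PGK1", "PPIA", "RPL13A", "TBP", "TUBB",
)

#: Named non-marker endogenous genes of biological interest in the screen
#: (factor-specific response genes: osteocalcin, metallopeptidases, BMP
#: antagonists, ...).
NAMED_ENDOGENOUS: tuple[str, ...] = (
    "BGLAP", "BMP4", "DPT", "FGFR1", "MMP1", "MMP7", "MMP13",
    "NOG", "NOTCH1", "PRG4", "SFRP4", "SOCS2", "SOX9", "TIMP4",
) + (
    # broad TGFB-superfamily response program of a chondrogenesis panel
    "ADAMTS4", "COL5A1", "COL6A1", "COL8A1", "CTGF", "FN1", "LOX",
    "POSTN", "SERPINE1", "SPARC", "TAGLN", "TGFBI", "THBS1", "TNC",
    "WISP1", "IL6", "MMP3", "PTGS2",
)

#: The part of the named program induced / repressed by TGFB ligands.
TGFB_PROGRAM_UP: tuple[str, ...] = (
    "ADAMTS4", "COL5A1", "COL6A1", "COL8A1", "CTGF", "FN1", "LOX",
    "POSTN", "SERPINE1", "SPARC", "TAGLN", "TGFBI", "THBS1", "TNC",
    "WISP1",
)
TGFB_PROGRAM_DOWN: tuple[str, ...] = ("IL6", "MMP3", "PTGS2")

#: Spike-in positive-control probes: nominal input concentrations form a
#: strictly decreasing geometric series (arbitrary units, ratio 4).
POSITIVE_CONTROLS: dict[str, float] = {
    "POS_A": 128.0, "POS_B": 32.0, "POS_C": 8.0,
    "POS_D": 2.0, "POS_E": 0.5, "POS_F": 0.125,
}

#: Negative-control (background) probes.
NEGATIVE_CONTROLS: tuple[str, ...] = tuple(f"NEG_{c}" for c in "ABCDEFGH")

#: Reserved pseudo-condition id for day-0 untreated cells.
UNTREATED_ID: int = 0

#: Default cell seeding density (cells per mL).
DEFAULT_DENSITY: float = 1.0e7

#: Densities of the density arm (cells per mL, log2 spaced around default).
DENSITY_ARM: tuple[float, ...] = (1.25e6, 2.5e6, 5.0e6, 2.0e7)

GENE_CLASSES = ("endogenous", "housekeeping_candidate", "positive_ctrl", "negative_ctrl")
MARKER_SETS = ("wanted", "unwanted", "other")

_MIN_PANEL = len(WANTED_MARKERS) + len(UNWANTED_MARKERS)


class PanelSizeError(ValueError):
    """Requested panel is too small to hold the curated marker sets."""


class DesignError(ValueError):
    """Design table and registry are inconsistent with the requested analysis."""


# ---------------------------------------------------------------------------
# Gene panel
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GenePanel:
    """Probe universe of a screen.

    Parameters
    ----------
    genes
        DataFrame indexed by gene symbol with columns ``cls`` (one of
        ``endogenous``, ``housekeeping_candidate``, ``positive_ctrl``,
        ``negative_ctrl``) and ``marker_set`` (``wanted`` / ``unwanted`` /
        ``other``).
    positive_ctrl_inputs
        Nominal spike-in input concentration per positive-control probe;
        must form a strictly decreasing series in probe order.
    """

    genes: pd.DataFrame
    positive_ctrl_inputs: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(POSITIVE_CONTROLS))

    def __post_init__(self) -> None:
        if self.genes.index.duplicated().any():
            dup = self.genes.index[self.genes.index.duplicated()][0]
            raise ValueError(f"duplicate gene symbol {dup!r} in panel")
        bad_cls = set(self.genes["cls"]) - set(GENE_CLASSES)
        if bad_cls:
            raise ValueError(f"unknown gene classes: {sorted(bad_cls)}")
        markers = self.genes["marker_set"].isin(("wanted", "unwanted"))
        if not (self.genes.loc[markers, "cls"] == "endogenous").all():
            raise ValueError("wanted/unwanted membership requires cls == 'endogenous'")
        conc = list(self.positive_ctrl_inputs.values())
        if any(b >= a for a, b in zip(conc, conc[1:])):
            raise ValueError("positive-control concentrations must strictly decrease")

    # -- convenience views --------------------------------------------------
    def symbols(self, cls: str) -> list[str]:
        return list(self.genes.index[self.genes["cls"] == cls])

    @property
    def wanted(self) -> list[str]:
        return list(self.genes.index[self.genes["marker_set"] == "wanted"])

    @property
    def unwanted(self) -> list[str]:
        return list(self.genes.index[self.genes["marker_set"] == "unwanted"])

    def marker_set(self, name: str) -> list[str]:
        if name == "wanted":
            return self.wanted
        if name == "unwanted":
            return self.unwanted
        raise KeyError(f"unknown marker set {name!r}")

    @property
    def assay_symbols(self) -> list[str]:
        """Endogenous + housekeeping-candidate symbols (the counted genes)."""
        mask = self.genes["cls"].isin(("endogenous", "housekeeping_candidate"))
        return list(self.genes.index[mask])

    @property
    def housekeeping_candidates(self) -> list[str]:
        return self.symbols("housekeeping_candidate")

    @property
    def positive_controls(self) -> list[str]:
        return self.symbols("positive_ctrl")

    @property
    def negative_controls(self) -> list[str]:
        return self.symbols("negative_ctrl")

    @property
    def n_endogenous(self) -> int:
        return len(self.assay_symbols)

    # -- serialization ------------------------------------------------------
    def to_tsv(self, path) -> None:
        df = self.genes.copy()
        df["pos_input"] = [self.positive_ctrl_inputs.get(s, "") for s in df.index]
        df.to_csv(path, sep="\t", index_label="symbol")

    @classmethod
    def from_tsv(cls, path) -> "GenePanel":
        df = pd.read_csv(path, sep="\t", index_col="symbol")
        pos = {s: float(v) for s, v in df["pos_input"].items()
               if v != "" and pd.notna(v)}
        return cls(df[["cls", "marker_set"]], pos or dict(POSITIVE_CONTROLS))


def build_default_panel(n_genes: int = 364, seed: int = 0) -> GenePanel:
    """Build the default screening panel of ``n_genes`` counted genes.

    The panel is filled in a fixed priority order: the 14 wanted and 11
    unwanted markers, then named housekeeping candidates, then named
    response genes, then synthetic filler symbols (``GENE#####``, drawn
    from the seed so two seeds give different filler but identical
    marker/control content).  Fixed positive/negative control probes are
    appended on top of ``n_genes``.
    """
    if n_genes < _MIN_PANEL:
        raise PanelSizeError(
            f"n_genes={n_genes} cannot hold the curated marker sets; "
            f"minimum is {_MIN_PANEL}")
    rows: list[tuple[str, str, str]] = []
    for s in WANTED_MARKERS:
        rows.append((s, "endogenous", "wanted"))
    for s in UNWANTED_MARKERS:
        rows.append((s, "endogenous", "unwanted"))
    for s in HOUSEKEEPING_CANDIDATES:
        if len(rows) >= n_genes:
            break
        rows.append((s, "housekeeping_candidate", "other"))
    for s in NAMED_ENDOGENOUS:
        if len(rows) >= n_genes:
            break
        rows.append((s, "endogenous", "other"))
    n_fill = n_genes - len(rows)
    if n_fill > 0:
        rng = np.random.default_rng(seed)
        nums = rng.choice(99999, size=n_fill, replace=False) + 1
        for n in np.sort(nums):
            rows.append((f"GENE{n:05d}", "endogenous", "other"))
    for s in POSITIVE_CONTROLS:
        rows.append((s, "positive_ctrl", "other"))
    for s in NEGATIVE_CONTROLS:
        rows.append((s, "negative_ctrl", "other"))
    genes = pd.DataFrame(rows, columns=["symbol", "cls", "marker_set"])
    genes = genes.set_index("symbol")
    return GenePanel(genes)


# ---------------------------------------------------------------------------
# Conditions and registry
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Condition:
    """One screening condition: factor levels, seeding density and arm."""

    id: int
    tgfb: str | None = None      # None, "TGFB1", "TGFB2" or "TGFB3"
    bmp: str | None = None       # None, "BMP2", "BMP4" or "BMP6"
    dex: bool = False
    igf1: bool = False
    fgf2: bool = False
    density: float = DEFAULT_DENSITY
    arm: str = "factorial"       # factorial / isoform / density / untreated

    def active(self, token: str) -> bool:
        """True if a factor token is active in this condition.

        ``TGFB`` / ``BMP`` match any isoform; ``TGFB1`` / ``BMP4`` etc.
        match the specific isoform; ``DEX`` / ``IGF1`` / ``FGF2`` match
        presence.
        """
        if token == "TGFB":
            return self.tgfb is not None
        if token == "BMP":
            return self.bmp is not None
        if token in ("TGFB1", "TGFB2", "TGFB3"):
            return self.tgfb == token
        if token in ("BMP2", "BMP4", "BMP6"):
            return self.bmp == token
        if token == "DEX":
            return self.dex
        if token == "IGF1":
            return self.igf1
        if token == "FGF2":
            return self.fgf2
        raise KeyError(f"unknown factor token {token!r}")

    def term_active(self, term: str) -> bool:
        """True if every factor in a ``A:B``-style term is active."""
        return all(self.active(tok) for tok in term.split(":"))

    @property
    def factor_set(self) -> frozenset[str]:
        """Canonical factorial-arm factor presence (isoform-agnostic for
        TGFB/BMP families mapped onto the TGFB1/BMP2 design columns)."""
        present = set()
        if self.tgfb is not None:
            present.add("TGFB1")
        if self.fgf2:
            present.add("FGF2")
        if self.dex:
            present.add("DEX")
        if self.igf1:
            present.add("IGF1")
        if self.bmp is not None:
            present.add("BMP2")
        return frozenset(present)


def condition_number(present: Iterable[str],
                     weights: Mapping[str, int] | None = None) -> int:
    """Canonical condition id of a factor-presence subset (factorial arm)."""
    weights = dict(weights or NUMBERING_WEIGHTS)
    present = set(present)
    unknown = present - set(weights)
    if unknown:
        raise KeyError(f"unknown factors {sorted(unknown)}")
    return 32 - sum(weights[f] for f in present)


class ConditionRegistry:
    """The 48 screening conditions plus the reserved untreated condition."""

    def __init__(self, conditions: Sequence[Condition], untreated: Condition):
        self._by_id = {c.id: c for c in conditions}
        if len(self._by_id) != len(conditions):
            raise ValueError("duplicate condition ids")
        self.untreated = untreated
        self._by_id[untreated.id] = untreated

    def __len__(self) -> int:
        return len(self._by_id) - 1      # untreated pseudo-condition excluded

    def __contains__(self, cid: int) -> bool:
        return cid in self._by_id

    def lookup(self, cid: int) -> Condition:
        try:
            return self._by_id[cid]
        except KeyError:
            raise KeyError(f"condition id {cid} not in registry") from None

    @property
    def ids(self) -> list[int]:
        return sorted(i for i in self._by_id if i != self.untreated.id)

    @property
    def factorial_ids(self) -> list[int]:
        return [i for i in self.ids if self._by_id[i].arm == "factorial"]

    def arm_ids(self, arm: str) -> list[int]:
        return [i for i in self.ids if self._by_id[i].arm == arm]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid in [self.untreated.id] + self.ids:
            c = self._by_id[cid]
            rows.append({
                "id": c.id, "tgfb": c.tgfb or "", "bmp": c.bmp or "",
                "dex": int(c.dex), "igf1": int(c.igf1), "fgf2": int(c.fgf2),
                "density": c.density, "arm": c.arm,
            })
        return pd.DataFrame(rows).set_index("id")

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def enumerate_factorial(k: int) -> list[tuple[int, ...]]:
    """All 2^k on/off combinations in standard (Yates) order.

    The first factor cycles fastest; the first row is all-off, the last
    all-on.
    """
    if not 1 <= k <= 10:
        raise ValueError(f"k must be in 1..10, got {k}")
    out = []
    for i in range(2 ** k):
        out.append(tuple((i >> j) & 1 for j in range(k)))
    return out


def build_condition_registry(
        weights: Mapping[str, int] | None = None) -> ConditionRegistry:
    """Build the default 48-condition registry.

    Conditions 1..32 are the full 2^5 factorial arm under the canonical
    numbering; 33..38 are the TGFB2/TGFB3 isoform conditions (each alone,
    +DEX, +DEX+BMP2); 39..44 the BMP4/BMP6 isoform conditions (each alone,
    +TGFB1, +TGFB1+DEX); 45..48 the density arm (1.25, 2.5, 5, 20 x 10^6
    cells/mL under TGFB1+DEX+BMP2).
    """
    conds: list[Condition] = []
    for bits in itertools.product((0, 1), repeat=5):
        t, f, d, i, b = bits
        present = {name for name, on in zip(FACTORS, bits) if on}
        cid = condition_number(present, weights)
        conds.append(Condition(
            id=cid,
            tgfb="TGFB1" if t else None,
            bmp="BMP2" if b else None,
            dex=bool(d), igf1=bool(i), fgf2=bool(f),
            arm="factorial"))
    cid = 33
    for iso in ("TGFB2", "TGFB3"):
        for dex, bmp in ((False, None), (True, None), (True, "BMP2")):
            conds.append(Condition(id=cid, tgfb=iso, bmp=bmp, dex=dex,
                                   arm="isoform"))
            cid += 1
    for iso in ("BMP4", "BMP6"):
        for tgfb, dex in ((None, False), ("TGFB1", False), ("TGFB1", True)):
            conds.append(Condition(id=cid, tgfb=tgfb, bmp=iso, dex=dex,
                                   arm="isoform"))
            cid += 1
    for dens in DENSITY_ARM:
        conds.append(Condition(id=cid, tgfb="TGFB1", bmp="BMP2", dex=True,
                               density=dens, arm="density"))
        cid += 1
    untreated = Condition(id=UNTREATED_ID, arm="untreated")
    return ConditionRegistry(conds, untreated)


# ---------------------------------------------------------------------------
# Design table
# ---------------------------------------------------------------------------

def make_design_table(registry: ConditionRegistry,
                      n_donors: int = 3,
                      days: Sequence[int] = (0, 1, 7),
                      arms: Sequence[str] = ("factorial", "isoform", "density"),
                      ) -> pd.DataFrame:
    """Sample -> (condition, donor, day, lane) mapping of a screen.

    Day-0 samples carry the reserved untreated pseudo-condition (one per
    donor); days 1 and 7 contain every registry condition of the chosen
    arms for every donor.
    """
    cids = [i for i in registry.ids if registry.lookup(i).arm in arms]
    rows = []
    lane = 0
    for donor in range(1, n_donors + 1):
        for day in days:
            day_cids = [UNTREATED_ID] if day == 0 else cids
            for cid in day_cids:
                lane += 1
                rows.append({
                    "sample_id": f"D{donor}d{day}c{cid:02d}",
                    "condition_id": cid, "donor": donor,
                    "day": day, "lane": lane,
                })
    design = pd.DataFrame(rows).set_index("sample_id")
    validate_design(design, registry)
    return design


def validate_design(design: pd.DataFrame, registry: ConditionRegistry) -> None:
    missing = set(design["condition_id"]) - set(registry.ids) - {UNTREATED_ID}
    if missing:
        raise DesignError(f"condition ids not in registry: {sorted(missing)}")
    key = design[["condition_id", "donor", "day"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0]
        raise DesignError(
            f"duplicate (condition, donor, day) combination: {tuple(dup)}")


# ---------------------------------------------------------------------------
# Coded model matrices
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ModelMatrix:
    """Coded factorial model matrix with term metadata.

    ``X`` holds intercept, +-1 coded main-effect and interaction columns
    and 0/1 donor-block columns; ``terms`` names the effect columns (in
    ``X`` column order, excluding intercept and blocks) and ``orders``
    their interaction order.
    """

    X: pd.DataFrame
    terms: list[str]
    orders: dict[str, int]
    block_cols: list[str]

    @property
    def n_obs(self) -> int:
        return len(self.X)


def coded_model_matrix(levels: pd.DataFrame, max_order: int,
                       blocks: pd.Series | None = None) -> ModelMatrix:
    """Build a +-1 coded model matrix from a boolean factor-level table.

    ``levels`` is observations x factors (True = factor present);
    interaction columns up to ``max_order`` are element-wise products of
    the main-effect columns; ``blocks`` adds 0/1 indicator columns for
    every block level except the first.
    """
    if not 1 <= max_order <= len(levels.columns):
        raise ValueError(f"max_order must be in 1..{len(levels.columns)}")
    coded = levels.astype(int) * 2 - 1
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(levels), dtype=int)}
    terms: list[str] = []
    orders: dict[str, int] = {}
    names = list(levels.columns)
    for order in range(1, max_order + 1):
        for combo in itertools.combinations(names, order):
            term = ":".join(combo)
            col = np.ones(len(levels), dtype=int)
            for f in combo:
                col = col * coded[f].to_numpy()
            cols[term] = col
            terms.append(term)
            orders[term] = order
    block_cols: list[str] = []
    if blocks is not None:
        lvls = sorted(pd.unique(blocks))
        for lv in lvls[1:]:
            name = f"block[{lv}]"
            cols[name] = (blocks == lv).astype(int).to_numpy()
            block_cols.append(name)
    X = pd.DataFrame(cols, index=levels.index)
    return ModelMatrix(X=X, terms=terms, orders=orders, block_cols=block_cols)


def encode_model_matrix(design: pd.DataFrame, registry: ConditionRegistry,
                        max_order: int = 3) -> ModelMatrix:
    """Coded model matrix for the factorial arm of a design table.

    Raises :class:`DesignError` if any design row refers to a
    non-factorial condition.
    """
    if max_order not in (1, 2, 3):
        raise ValueError(f"max_order must be 1, 2 or 3, got {max_order}")
    bad = [cid for cid in design["condition_id"].unique()
           if registry.lookup(int(cid)).arm != "factorial"]
    if bad:
        raise DesignError(
            f"non-factorial conditions present in design: {sorted(bad)}")
    levels = pd.DataFrame(
        {f: [registry.lookup(int(c)).active(f) for c in design["condition_id"]]
         for f in FACTORS},
        index=design.index)
    blocks = design["donor"] if design["donor"].nunique() > 1 else None
    return coded_model_matrix(levels, max_order, blocks=blocks)
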