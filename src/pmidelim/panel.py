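"""Marker-panel configuration.

A panel describes which assays (Western blots, casein zymogram) are run per
case, which bands each lane is expected to show, and which of those bands
are degradation products (the markers) versus native proteins (QC).  The
default panel covers the four-assay muscle-protein setup:

* tropomyosin blot — stable native doublet at ~36–38 kDa, no degradation
  products over the observed range (negative control);
* cardiac troponin T (cTnT) blot — native doublet at 40–50 kDa, degradation
  products dp1 (~38 kDa) and dp2 (~33 kDa);
* desmin blot — native triplet at 45–55 kDa, degradation products dp1
  (~38 kDa), dp2 (~35 kDa), dp3 (~32 kDa) appearing consecutively;
* casein zymography — native calpain 1 and calpain 2 bands plus the
  autolyzed (activated) calpain 1 band between them; the zymogram carries
  no molecular-weight ladder, so its windows are in lane-position units.

Band windows default to ±1.5 kDa around the nominal weights, which are
approximate by nature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import yaml

from .densitometry import BandWindow

__all__ = ["Product", "Assay", "Panel", "default_panel", "DEFAULT_MW_HALF_WIDTH"]

DEFAULT_MW_HALF_WIDTH = 1.5  # kDa


@dataclass(frozen=True)
class Product:
    """One band of an assay: a native protein or a degradation product."""

    name: str
    role: str  # "native" | "dp"
    window: BandWindow

    def __post_init__(self):
        if self.role not in ("native", "dp"):
            raise ValueError(f"product {self.name}: role must be 'native' or 'dp'")
        if self.window.name != self.name:
            raise ValueError(f"product {self.name}: window name mismatch")


@dataclass(frozen=True)
class Assay:
    name: str
    products: tuple[Product, ...]

    def __init__(self, name: str, products: Iterable[Product]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "products", tuple(products))


@dataclass(frozen=True)
class Panel:
    """Full marker panel: assays plus product nesting chains.

    ``nesting`` lists chains of degradation products that appear
    consecutively (a later product is never observed without the earlier
    ones)."""

    assays: tuple[Assay, ...]
    nesting: tuple[tuple[str, ...], ...] = ()

    def __init__(self, assays: Iterable[Assay], nesting=()):
        object.__setattr__(self, "assays", tuple(assays))
        object.__setattr__(self, "nesting", tuple(tuple(c) for c in nesting))
        names = [p.name for a in self.assays for p in a.products]
        if len(names) != len(set(names)):
            raise ValueError("duplicate product names across assays")

    @property
    def degradation_products(self) -> tuple[str, ...]:
        return tuple(
            p.name for a in self.assays for p in a.products if p.role == "dp"
        )

    def assay_of(self, product: str) -> str:
        for a in self.assays:
            for p in a.products:
                if p.name == product:
                    return a.name
        raise KeyError(product)

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        def window_dict(w: BandWindow) -> dict:
            if w.is_mw:
                return {"mw_lo": w.mw_lo, "mw_hi": w.mw_hi}
            return {"pos_lo": w.pos_lo, "pos_hi": w.pos_hi}

        return {
            "assays": [
                {
                    "name": a.name,
                    "products": [
                        {"name": p.name, "role": p.role, **window_dict(p.window)}
                        for p in a.products
                    ],
                }
                for a in self.assays
            ],
            "nesting": [list(c) for c in self.nesting],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Panel":
        assays = []
        for a in d["assays"]:
            products = []
            for p in a["products"]:
                kwargs = {}
                if "mw" in p:  # nominal weight with default half-width
                    half = p.get("half_width", DEFAULT_MW_HALF_WIDTH)
                    kwargs = {"mw_lo": p["mw"] - half, "mw_hi": p["mw"] + half}
                else:
                    for k in ("mw_lo", "mw_hi", "pos_lo", "pos_hi"):
                        if k in p:
                            kwargs[k] = p[k]
                products.append(
                    Product(p["name"], p["role"], BandWindow(p["name"], **kwargs))
                )
            assays.append(Assay(a["name"], products))
        return cls(assays, d.get("nesting", ()))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Panel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _mw(name: str, role: str, mw: float, half: float = DEFAULT_MW_HALF_WIDTH) -> Product:
    return Product(name, role, BandWindow(name, mw_lo=mw - half, mw_hi=mw + half))


def _mw_range(name: str, role: str, lo: float, hi: float) -> Product:
    return Product(name, role, BandWindow(name, mw_lo=lo, mw_hi=hi))


def _pos(name: str, role: str, lo: float, hi: float) -> Product:
    return Product(name, role, BandWindow(name, pos_lo=lo, pos_hi=hi))


def default_panel() -> Panel:
    """The four-assay muscle degradation panel with nominal band weights."""
    return Panel(
        assays=[
            Assay("tropomyosin", [_mw_range("tropomyosin_native", "native", 34.5, 39.5)]),
            Assay(
                "ctnt",
                [
                    _mw_range("ctnt_native", "native", 40.0, 50.0),
                    _mw("ctnt_dp1", "dp", 38.0),
                    _mw("ctnt_dp2", "dp", 33.0),
                ],
            ),
            Assay(
                "desmin",
                [
                    _mw_range("desmin_native", "native", 45.0, 55.0),
                    _mw("desmin_dp1", "dp", 38.0),
                    _mw("desmin_dp2", "dp", 35.0),
                    _mw("desmin_dp3", "dp", 32.0),
                ],
            ),
            Assay(
                "zymography",
                [
                    # no ladder on casein zymograms: windows in position units,
                    # the activated calpain 1 band sits between the natives
                    _pos("calpain1_native", "native", 40.0, 46.0),
                    _pos("calpain1_dp", "dp", 48.0, 54.0),
                    _pos("calpain2_native", "native", 56.0, 62.0),
                ],
            ),
        ],
        nesting=[("desmin_dp1", "desmin_dp2", "desmin_dp3")],
    )
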