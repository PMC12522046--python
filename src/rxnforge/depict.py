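"""Molecule depiction backend.

Contract: given a SMILES and a target scale, report the tile size the
depiction will occupy (used by the layout engine before any rasterization)
and draw the molecule into exactly that tile.  The default backend is
RDKit's cairo drawer; sizes are derived from the 2D conformer extent so the
same (smiles, scale) pair always yields the same tile.
"""

from __future__ import annotations

import io
import math
from typing import Optional

from PIL import Image
from rdkit import Chem
from rdkit.Chem import rdDepictor
from rdkit.Chem.Draw import rdMolDraw2D


class DepictionError(RuntimeError):
    """Raised when a SMILES cannot be parsed or drawn; names the SMILES."""


class RDKitDepictor:
    """Deterministic RDKit-based depiction with a size cache.

    ``base_bond_px`` fixes pixels per bond length at scale 1.0; the style
    draw's molecule scale multiplies it.
    """

    base_bond_px: float = 32.0
    pad_px: int = 14
    min_side: int = 46

    def __init__(self) -> None:
        self._extent_cache: dict[str, tuple[float, float]] = {}

    def _extent(self, smiles: str) -> tuple[float, float]:
        """Width/height of the 2D conformer in bond-length units."""
        if smiles in self._extent_cache:
            return self._extent_cache[smiles]
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise DepictionError(f"SMILES {smiles!r} does not parse")
        rdDepictor.Compute2DCoords(mol)
        conf = mol.GetConformer()
        xs = [conf.GetAtomPosition(i).x for i in range(mol.GetNumAtoms())]
        ys = [conf.GetAtomPosition(i).y for i in range(mol.GetNumAtoms())]
        # RDKit 2D coords use a bond length of 1.5
        w = (max(xs) - min(xs)) / 1.5 if xs else 1.0
        h = (max(ys) - min(ys)) / 1.5 if ys else 1.0
        self._extent_cache[smiles] = (w, h)
        return (w, h)

    def size(self, smiles: str, scale: float) -> tuple[int, int]:
        """Tile size in pixels for this SMILES at this scale."""
        w, h = self._extent(smiles)
        px = self.base_bond_px * scale
        return (
            max(self.min_side, int(math.ceil(w * px)) + 2 * self.pad_px),
            max(self.min_side, int(math.ceil(h * px)) + 2 * self.pad_px),
        )

    def draw(
        self,
        smiles: str,
        width: int,
        height: int,
        line_width: int = 2,
    ) -> Image.Image:
        """Raster the molecule into an RGB tile of exactly (width, height)."""
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise DepictionError(f"SMILES {smiles!r} does not parse")
        try:
            drawer = rdMolDraw2D.MolDraw2DCairo(int(width), int(height))
            opts = drawer.drawOptions()
            opts.bondLineWidth = int(line_width)
            opts.padding = 0.06
            rdMolDraw2D.PrepareAndDrawMolecule(drawer, mol)
            drawer.FinishDrawing()
            png = drawer.GetDrawingText()
        except Exception as e:  # cairo failures surface with the SMILES attached
            raise DepictionError(f"failed to draw SMILES {smiles!r}: {e}") from e
        return Image.open(io.BytesIO(png)).convert("RGB")
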