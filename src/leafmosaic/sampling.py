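"""Patch subsampling, convergence summaries and trait reliability.

Tracing epidermal cells is slow, so how many cells are enough?  The
workflow here answers that empirically for any group of plants:

1. ``patch_sampler`` grows random contiguous patches of cells (whole
   stomatal complexes always included, edge cells never);
2. ``subsample_traits`` measures every trait on patches of increasing
   target size, many replicates each;
3. ``subsampling_summary`` computes, per trait and patch size, the SD
   of the patch-minus-whole-image differences (the delta values) on
   z-standardised traits; the patch size where this SD drops below a
   threshold (default 0.1) is the recommended minimum cell count;
4. ``trait_reliability`` scores each trait by the mean within-plant SD
   of its z-scores: 0 = perfectly repeatable within a plant, 1 =
   within-plant variation equals the variation of the whole dataset.
   Traits scoring above a threshold (default 0.2) are dropped.

Randomness is governed by one root seed; each (image, size, replicate)
replicate draws from its own counter-derived substream, so any single
patch is reproducible in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mosaic import GUARD_CLASS, PAVEMENT_CLASS, SUBSIDIARY_CLASS, CellMosaic
from .traits import (
    ImageTraitRecord,
    _PER_AREA,
    aggregate_cell_tables,
    extract_image_traits,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Patch",
    "PatchTraitTable",
    "patch_sampler",
    "patch_trait_vector",
    "subsample_traits",
    "subsampling_summary",
    "ConvergenceSummary",
    "z_transform",
    "trait_reliability",
    "ReliabilityReport",
]


@dataclass(frozen=True)
class Patch:
    """A connected patch of non-edge cells containing whole complexes."""

    patch_id: int
    seed_cell: int
    member_ids: frozenset[int]
    n_pavement: int
    n_stomata: int
    n_subsidiary: int
    rng_seed: object


def _eligible_cells(mosaic: CellMosaic) -> tuple[set[int], dict[int, frozenset[int]]]:
    """Non-edge cells, excluding members of edge-clipped complexes.

    Returns the eligible id set and a map cell_id -> full member set of
    its complex (for whole-complex inclusion).
    """
    complex_members: dict[int, frozenset[int]] = {}
    blocked: set[int] = set()
    for cx in mosaic.complexes:
        if cx.is_edge:
            blocked |= set(cx.member_ids)
        else:
            for cid in cx.member_ids:
                complex_members[cid] = cx.member_ids
    eligible = {
        cid
        for cid, c in mosaic.cells.items()
        if not c.is_edge and cid not in blocked
    }
    return eligible, complex_members


def patch_sampler(
    mosaic: CellMosaic,
    target_size: int,
    rng_seed,
    patch_id: int = 0,
) -> Patch:
    """Grow one random contiguous patch to at least ``target_size`` cells.

    A random non-edge cell seeds the patch; whole neighbour rings are
    added per iteration (so the final size may overshoot the target),
    any partially-touched stomatal complex is completed, and edge cells
    are never included.
    """
    eligible, complex_members = _eligible_cells(mosaic)
    if len(eligible) < target_size:
        raise ValueError(
            f"mosaic has only {len(eligible)} usable (non-edge) cells; "
            f"cannot grow a patch of {target_size}"
        )
    rng = np.random.default_rng(rng_seed)
    seed_cell = int(rng.choice(sorted(eligible)))
    members: set[int] = {seed_cell}
    members |= complex_members.get(seed_cell, frozenset())
    while len(members) < target_size:
        ring: set[int] = set()
        for cid in members:
            ring |= set(mosaic.adjacency.neighbors(cid))
        ring = (ring & eligible) - members
        if not ring:
            raise ValueError(
                f"patch growth exhausted at {len(members)} cells "
                f"(target {target_size}); mosaic region too small or disconnected"
            )
        for cid in ring:
            members.add(cid)
            members |= complex_members.get(cid, frozenset())
    classes = {cid: mosaic.cells[cid].cell_class for cid in members}
    return Patch(
        patch_id=patch_id,
        seed_cell=seed_cell,
        member_ids=frozenset(members),
        n_pavement=sum(1 for c in classes.values() if c == PAVEMENT_CLASS),
        n_stomata=sum(1 for c in classes.values() if c == GUARD_CLASS),
        n_subsidiary=sum(1 for c in classes.values() if c == SUBSIDIARY_CLASS),
        rng_seed=rng_seed,
    )


def patch_trait_vector(
    mosaic: CellMosaic,
    patch: Patch,
    record: ImageTraitRecord,
) -> dict[str, float]:
    """Trait vector measured on a patch only.

    Re-aggregates the whole-image per-cell tables restricted to patch
    members; stomatal north is re-used from the whole image (small
    patches may contain too few stomata to estimate it).
    """
    from . import arrangement

    members = patch.member_ids
    pav = record.pavement_cells[record.pavement_cells["cell_id"].isin(members)]
    in_complexes = [
        cx for cx in mosaic.complexes
        if not cx.is_edge and cx.member_ids <= members
    ]
    keep = {cx.complex_id for cx in in_complexes}
    sto = record.stomata[record.stomata["complex_id"].isin(keep)] if len(record.stomata) else record.stomata

    traits = aggregate_cell_tables(pav, sto)
    S = len(in_complexes)
    E = sum(1 for cid in members if mosaic.cells[cid].cell_class != GUARD_CLASS)
    traits["stomatal_index_pct"] = 100.0 * S / (S + E) if S + E else float("nan")
    area = sum(mosaic.cells[cid].area for cid in members)
    factor = _PER_AREA.get(mosaic.units, 1.0)
    traits["stomatal_density"] = S / (area / factor) if area > 0 else float("nan")
    traits["cell_density"] = E / (area / factor) if area > 0 else float("nan")

    sub = _submosaic(mosaic, members, in_complexes)
    zones = {
        cid: z
        for cid, z in zip(record.pavement_cells["cell_id"], record.pavement_cells["zone"])
        if cid in members
    }
    traits.update(arrangement.arrangement_traits(sub, record.north_deg, zones))
    traits["n_pavement"] = float(patch.n_pavement)
    traits["n_stomata_cells"] = float(patch.n_stomata)
    traits["n_subsidiary"] = float(patch.n_subsidiary)
    return traits


def _submosaic(mosaic: CellMosaic, members: frozenset[int], complexes) -> CellMosaic:
    """View of the mosaic restricted to patch members (for arrangement)."""
    sub = CellMosaic(
        cells={cid: mosaic.cells[cid] for cid in members},
        complexes=list(complexes),
        adjacency=mosaic.adjacency.subgraph(members),
        scale=mosaic.scale,
        units=mosaic.units,
        extent=mosaic.extent,
        measured_area=mosaic.measured_area,
        paired_guard_cells=mosaic.paired_guard_cells,
    )
    return sub


@dataclass
class PatchTraitTable:
    """Long-format patch measurements plus whole-image references."""

    table: pd.DataFrame
    reference: pd.DataFrame  # one row per image: whole-image trait values


def subsample_traits(
    mosaics: dict[str, CellMosaic] | CellMosaic,
    sizes: tuple[int, ...] = (50, 100, 200, 400),
    replicates: int = 100,
    rng_seed: int = 0,
    records: dict[str, ImageTraitRecord] | None = None,
) -> PatchTraitTable:
    """Measure traits on random patches of each target size.

    ``mosaics`` maps image ids to mosaics (a bare mosaic is treated as
    a single image).  Each (image, size, replicate) uses an independent
    counter-derived RNG substream of ``rng_seed``.  Infeasible sizes
    are skipped with a warning.
    """
    if isinstance(mosaics, CellMosaic):
        mosaics = {"image": mosaics}
    sizes = tuple(sorted(sizes))
    rows = []
    refs = []
    for img_idx, (image_id, mosaic) in enumerate(sorted(mosaics.items())):
        record = (
            records[image_id]
            if records is not None
            else extract_image_traits(mosaic, image_id=image_id)
        )
        refs.append({"image_id": image_id, **record.traits})
        for s_idx, size in enumerate(sizes):
            for rep in range(replicates):
                sub_seed = (int(rng_seed), img_idx, s_idx, rep)
                try:
                    patch = patch_sampler(mosaic, size, sub_seed, patch_id=rep)
                except ValueError as exc:
                    logger.warning("image %s size %d: %s; skipped", image_id, size, exc)
                    break
                rows.append(
                    {
                        "image_id": image_id,
                        "target_size": size,
                        "replicate": rep,
                        "actual_size": len(patch.member_ids),
                        **patch_trait_vector(mosaic, patch, record),
                    }
                )
    return PatchTraitTable(table=pd.DataFrame(rows), reference=pd.DataFrame(refs))


@dataclass
class ConvergenceSummary:
    """SD of delta values per (trait, size) and minimum cell counts."""

    sd_table: pd.DataFrame       # index: trait, columns: target sizes
    min_cells: pd.Series         # per trait; NaN = threshold never reached
    threshold: float
    scaled: bool                 # True when deltas are in z-units


_META_COLS = {
    "image_id", "target_size", "replicate", "actual_size",
    "n_pavement", "n_stomata_cells", "n_subsidiary",
}


def subsampling_summary(
    table: PatchTraitTable, threshold: float = 0.1
) -> ConvergenceSummary:
    """Convergence of patch measurements toward whole-image values.

    Traits are z-standardised with the mean and SD of the whole-image
    dataset (the reference rows); with a single image this scaling is
    undefined and raw deltas are used instead (with a warning).  For
    each trait and patch size the SD of the delta values (patch minus
    whole image) measures convergence; the minimum recommended cell
    count is the smallest size whose SD falls below ``threshold``.
    """
    df = table.table
    ref = table.reference.set_index("image_id")
    trait_cols = [
        c for c in df.columns
        if c not in _META_COLS and c in ref.columns and pd.api.types.is_numeric_dtype(df[c])
    ]
    scaled = len(ref) >= 2
    if scaled:
        mu = ref[trait_cols].mean()
        sd = ref[trait_cols].std(ddof=1)
        keep = [c for c in trait_cols if sd[c] > 0]
        dropped = sorted(set(trait_cols) - set(keep))
        if dropped:
            logger.warning("constant across images, not scaled: %s", dropped)
    else:
        logger.warning(
            "single image: whole-image-dataset scaling undefined; using raw deltas"
        )
        mu = pd.Series(0.0, index=trait_cols)
        sd = pd.Series(1.0, index=trait_cols)
        keep = trait_cols

    sizes = sorted(df["target_size"].unique())
    sd_rows = {}
    for trait in keep:
        row = {}
        for size in sizes:
            deltas = []
            for image_id, grp in df[df["target_size"] == size].groupby("image_id"):
                whole = ref.at[image_id, trait]
                d = (grp[trait] - whole) / sd[trait]
                deltas.append(d.to_numpy())
            deltas = np.concatenate(deltas) if deltas else np.array([])
            deltas = deltas[~np.isnan(deltas)]
            if len(deltas) < 3:
                row[size] = np.nan  # too few replicates: unstable
            else:
                row[size] = float(np.std(deltas, ddof=1))
        sd_rows[trait] = row
    sd_table = pd.DataFrame(sd_rows).T
    sd_table.columns.name = "target_size"

    min_cells = {}
    for trait in sd_table.index:
        hit = [s for s in sizes if sd_table.at[trait, s] < threshold]
        min_cells[trait] = float(hit[0]) if hit else np.nan
    return ConvergenceSummary(
        sd_table=sd_table,
        min_cells=pd.Series(min_cells, name="min_cells"),
        threshold=threshold,
        scaled=scaled,
    )


def z_transform(
    df: pd.DataFrame, group_columns: tuple[str, ...] = ()
) -> pd.DataFrame:
    """Center and scale every numeric trait column to mean 0, SD 1.

    Uses the global mean and SD (grouping columns are carried through
    untouched).  Constant columns are dropped with a warning; a single
    row is an error.
    """
    if len(df) < 2:
        raise ValueError("need at least two rows to standardise")
    out = df.copy()
    dropped = []
    for col in df.columns:
        if col in group_columns or not pd.api.types.is_numeric_dtype(df[col]):
            continue
        sd = df[col].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            dropped.append(col)
            out = out.drop(columns=col)
            continue
        out[col] = (df[col] - df[col].mean()) / sd
    if dropped:
        logger.warning("dropping constant/non-finite columns: %s", dropped)
    return out


@dataclass
class ReliabilityReport:
    """Per-trait reliability scores and the retained/dropped decision."""

    scores: pd.Series
    retained: pd.Series
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"score": self.scores, "retained": self.retained})


def trait_reliability(
    standardized: pd.DataFrame,
    plant_column: str = "plant",
    threshold: float = 0.2,
) -> ReliabilityReport:
    """Within-plant repeatability of z-standardised traits.

    Score per trait = mean over plants of the SD of that plant's
    replicate z-scores.  A score of 0.2 means the within-plant
    variation is 20% of the whole-dataset variation (reliable); a score
    of 1 means they are equal (unreliable).  Plants with a single image
    contribute no SD; at least one plant needs >= 2 images.
    """
    if plant_column not in standardized.columns:
        raise ValueError(f"missing plant column {plant_column!r}")
    counts = standardized.groupby(plant_column).size()
    if (counts >= 2).sum() == 0:
        raise ValueError("no plant has >= 2 images; reliability is undefined")
    trait_cols = [
        c for c in standardized.columns
        if c != plant_column and pd.api.types.is_numeric_dtype(standardized[c])
    ]
    within = standardized.groupby(plant_column)[trait_cols].std(ddof=1)
    scores = within.mean(axis=0, skipna=True)
    retained = scores <= threshold
    return ReliabilityReport(scores=scores, retained=retained, threshold=threshold)
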