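"""In-silico group experiments built on the generator and measurement stages.

The swelling experiment mirrors the imaging comparison between control and
conditional-knockout astrocytes: the "swollen" group is simulated with process
radii scaled up (default x1.2) while the branching program (branch count,
lengths, bifurcations) is left untouched. Volumes should separate; the
per-radius Sholl profiles should not -- the volume-up / branching-unchanged
dissociation characteristic of osmotic swelling rather than structural
remodeling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import LabelVolume
from .morphometry import (
    instance_surface_area,
    instance_volume,
    skeletonize_cell,
    sholl_profile,
    soma_volume,
)
from .synthgen import SimulationConfig, rasterize, sample_tree

__all__ = ["measure_single_cells", "swelling_experiment"]


def _cell_grid(cfg: SimulationConfig):
    """Geometry of a single-cell grid large enough for any sampled tree."""
    reach = (
        cfg.soma_radius_um[1]
        + 1.2 * cfg.branch_length_um[1] * (1 + cfg.bifurcation_prob)
        + 4.0
    )
    spacing = cfg.spacing
    half = np.array([reach, reach, reach])
    shape = tuple(int(np.ceil(2 * h / s)) + 1 for h, s in zip(half, spacing))
    center = half
    return shape, spacing, center


def measure_single_cells(
    cfg: SimulationConfig,
    n_cells: int,
    n_animals: int,
    group: str,
    seed: int,
    sholl_step_um: float = 2.0,
    sholl_r_max_um: float = 30.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rasterize and measure ``n_cells`` independent cells, each in its own
    grid (no placement constraints, no axial truncation).

    Returns (morphometry table, long-format Sholl table); cells are assigned
    round-robin to ``n_animals`` animals.
    """
    rng = np.random.default_rng(seed)
    shape, spacing, center = _cell_grid(cfg)
    records, sholl_rows = [], []
    for i in range(n_cells):
        tree = sample_tree(cfg, center, rng)
        labels, cells = rasterize([tree], shape, spacing, (0, 0, 0))
        lab = LabelVolume(labels.labels, spacing)
        vol = instance_volume(lab, 1)
        area = instance_surface_area(lab, 1)
        soma = soma_volume(lab, 1, tree.soma_center)
        g = skeletonize_cell(lab.labels == 1, spacing)
        profile = sholl_profile(g, tree.soma_center, sholl_step_um, sholl_r_max_um)
        records.append(
            {
                "cell_id": i + 1,
                "group": group,
                "animal_id": f"{group}_{i % n_animals + 1}",
                "volume_um3": vol,
                "area_um2": area,
                "soma_um3": soma,
            }
        )
        for r, c in zip(profile.radii_um, profile.counts):
            sholl_rows.append(
                {"cell_id": i + 1, "group": group, "radius_um": float(r),
                 "intersections": int(c)}
            )
    return pd.DataFrame(records), pd.DataFrame(sholl_rows)


def swelling_experiment(
    seed: int = 0,
    n_cells_per_group: int = 15,
    n_animals: int = 5,
    radius_scale: float = 1.2,
    config: SimulationConfig | None = None,
) -> dict:
    """Simulate a control and a process-swollen group and compare them.

    The group sizes follow the imaging design (5 animals, ~3 cells each).
    Returns the swelling report plus the underlying tables.
    """
    from .stats import swelling_report

    base = config or SimulationConfig()
    swollen = SimulationConfig(**{**base.to_dict(),
                                  "process_radius_scale":
                                  base.process_radius_scale * radius_scale})
    ctr, ctr_sholl = measure_single_cells(base, n_cells_per_group, n_animals,
                                          "CTR", seed)
    cko, cko_sholl = measure_single_cells(swollen, n_cells_per_group, n_animals,
                                          "cKO", seed + 104729)
    report = swelling_report(ctr, cko, ctr_sholl, cko_sholl)
    return {"report": report, "ctr": ctr, "cko": cko,
            "ctr_sholl": ctr_sholl, "cko_sholl": cko_sholl}
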