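"""Shared synthetic-crystal fixtures.

Crystals are generated once per session; tests must not mutate them.
"""

import numpy as np
import pytest

from mrpilot.toycrystal import (ComponentGen, GenSpec, generate_crystal,
                                truth_models)


@pytest.fixture(scope="session")
def small_crystal():
    """Two copies of one 24-residue component in P212121, noiseless."""
    gs = GenSpec(components=(ComponentGen("A", 24, 2),),
                 space_group="P212121", epsilon=0.0)
    return generate_crystal(gs, seed=3)


@pytest.fixture(scope="session")
def noisy_crystal():
    """Same geometry with the default score noise enabled."""
    gs = GenSpec(components=(ComponentGen("A", 24, 2),),
                 space_group="P212121")
    return generate_crystal(gs, seed=3)


@pytest.fixture(scope="session")
def polar_crystal():
    """One copy in P21 (continuous origin along b), noiseless."""
    gs = GenSpec(components=(ComponentGen("A", 24, 2),),
                 space_group="P21", epsilon=0.0)
    return generate_crystal(gs, seed=4)


def truths_and_models(case):
    crystal = case.crystal
    return [p for _c, p in crystal.truths], truth_models(crystal)


def placements_match_truths(placements, crystal, tol_rot=2.0,
                            tol_trans=0.5):
    """Each placement sits on a distinct truth image (symmetry + origin).

    Copies of one solution may legitimately occupy images of their
    truths under different crystal operators; the check is therefore
    per placement, over all operator x origin-shift images, with
    distinct truths consumed.
    """
    import numpy as np
    from mrpilot.symmetry import (apply_symop, min_image_distance,
                                  rotation_angle_between)
    sg, cell = crystal.sg, crystal.cell
    used = set()
    for bp in placements:
        hit = None
        for k, (comp, tp) in enumerate(crystal.truths):
            if k in used or comp != bp.component_id:
                continue
            for op in sg.ops:
                img = apply_symop(tp, op, cell)
                if rotation_angle_between(bp.rot, img.rot) > tol_rot:
                    continue
                for shift in sg.origin_shifts:
                    t2 = img.trans + cell.orth @ np.asarray(shift)
                    if min_image_distance(bp.trans - t2, cell, sg) \
                            <= tol_trans:
                        hit = k
                        break
                if hit is not None:
                    break
            if hit is not None:
                break
        if hit is None:
            return False
        used.add(hit)
    return True
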