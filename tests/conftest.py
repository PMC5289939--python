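import numpy as np
import pytest

from yapscreen import (
    CellPlacement,
    FieldLayout,
    PlateSpec,
    PopulationSpec,
    ScreenSpec,
    TreatmentSpec,
    render_field,
)

#: 12 control densities spanning a 4-fold range (cells per well).
CONTROL_DENSITIES = tuple(float(x) for x in np.geomspace(125, 500, 12))


def normal_equations_fit(X: np.ndarray, y: np.ndarray):
    """Independent OLS oracle: solve (X'X) b = X'y with an intercept column.

    Returns (beta, se) with the intercept first, then one entry per column
    of X, independent of the statsmodels path used by the package.
    """
    A = np.column_stack([np.ones(len(X)), X])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    resid = y - A @ beta
    dof = len(y) - A.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(A.T @ A)))
    return beta, se


def make_screen_spec(
    seed: int,
    targets=(),
    replicate_rule: str = "2of2",
    control_densities=CONTROL_DENSITIES,
    noise_sd: float = 0.1054,
):
    """Build a one-plate screen spec.

    ``targets`` is a list of dicts with keys: name, delta (direct offset),
    feature_means (mean overrides), density (cells/well, default 500).
    """
    n_rep = {"2of2": 2, "3of4": 4}[replicate_rule]
    base = PopulationSpec(noise_sd=noise_sd, seed=seed)
    treatments = []
    for t in targets:
        pop = base.with_(
            seeding_density=float(t.get("density", 500.0)),
            direct_effect_delta=float(t.get("delta", 0.0)),
            feature_means=t.get("feature_means", {}),
        )
        treatments.append(
            TreatmentSpec(
                target=t["name"],
                n_replicates=n_rep,
                population=pop,
                kind="direct" if t.get("delta") else "indirect",
            )
        )
    plate = PlateSpec(
        plate_id="P1", control_densities=list(control_densities), treatments=treatments
    )
    return ScreenSpec(
        plates=[plate], replicate_rule=replicate_rule,
        control_population=base, seed=seed,
    )


@pytest.fixture(scope="session")
def single_cell_field():
    """One isolated round cell, zero target ratio, no blur or noise."""
    layout = FieldLayout(
        shape=(128, 128),
        placements=[
            CellPlacement(center=(64.0, 64.0), cell_radius=40.0,
                          nucleus_radii=(12.0, 12.0), target_ratio=0.0)
        ],
    )
    return render_field(layout)


@pytest.fixture(scope="session")
def touching_pair_field():
    """Two cells whose territories abut along the Voronoi bisector."""
    layout = FieldLayout(
        shape=(128, 192),
        placements=[
            CellPlacement(center=(64.0, 70.0), cell_radius=45.0,
                          nucleus_radii=(10.0, 10.0), target_ratio=0.3),
            CellPlacement(center=(64.0, 122.0), cell_radius=45.0,
                          nucleus_radii=(10.0, 10.0), target_ratio=-0.2),
        ],
    )
    return render_field(layout)
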