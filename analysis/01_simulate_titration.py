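"""Simulate the replacement titration and locate the stoichiometry fingerprints.

Runs both binding schemes (sequential and two-independent-site) with tight
binding at the experimental concentrations (0.6 mM client, 2.1 mM chaperone
stock), writes the species profiles, and reports where the singly and
doubly bound complexes are maximal along the chaperone:client ratio axis.
"""

from pathlib import Path

from chapbind.equilibria import BindingModel, EquilibriumParams
from chapbind.titration import (
    DEFAULT_TARGET_RATIOS,
    plan_protocol,
    profile_maximum,
    run_dense_titration,
    run_titration,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
K_UN, KD = 22.7, 1e-9
N_T0, K_STOCK = 6e-4, 2.1e-3


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    params = EquilibriumParams(K_UN, KD, KD)
    lines = ["model,observable,ratio_at_max"]
    for model in BindingModel:
        discrete = run_titration(
            plan_protocol(DEFAULT_TARGET_RATIOS, N_T0, K_STOCK), params, model
        )
        discrete.to_csv(RESULTS / f"titration_{model.value}_discrete.csv")

        dense = run_dense_titration(params, model, N_T0, K_STOCK)
        dense.to_csv(RESULTS / f"titration_{model.value}_dense.csv")

        r1, _ = profile_maximum(dense.ratios, dense.bound_1to1_series(population=True))
        r2, _ = profile_maximum(dense.ratios, dense.bound_2to1_series())
        lines += [
            f"{model.value},population_1to1,{r1:.4f}",
            f"{model.value},concentration_2to1,{r2:.4f}",
        ]
        print(
            f"{model.value} model: 1:1 complex population peaks at ratio {r1:.3f}, "
            f"2:1 complex concentration peaks at ratio {r2:.3f}"
        )
    (RESULTS / "titration_maxima.csv").write_text("\n".join(lines) + "\n")
    print(
        "The two distinct maxima (~1 and ~2) are the fingerprints that separate "
        "singly from doubly bound chaperone-client complexes."
    )


if __name__ == "__main__":
    main()
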