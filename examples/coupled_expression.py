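"""Population-level expression by superposing the episode look-up table.

Couples the deterministic episode to a 2,000-cell distribution run and
prints the induction-state census plus the transcript settling level.
"""

import numpy as np

from strpfr import (
    ReactorConfig,
    SimulationParameters,
    default_trp_operon,
    mean_induction_census,
    population_trajectory,
    run_population,
    simulate_episode,
)

episode = simulate_episode(SimulationParameters(), default_trp_operon())
pop = run_population(ReactorConfig(n0=2000), duration=2 * 3600.0, seed=4)

grid = np.arange(0.0, 2 * 3600.0 + 1, 60.0)
expr = population_trajectory(pop, episode, grid)
census = mean_induction_census(pop, episode, 1800.0, 7200.0, 60.0)

mrna = expr.mrna_per_cell.sum(axis=0)
print(f"episode length              : {episode.episode_length:.0f} s")
print(f"per-capita mRNA at 10 min   : {mrna[10]:.2f} copies")
print(f"per-capita mRNA, final hour : {mrna[grid >= 3600].mean():.2f} copies")
print("census (not/once/multiple)  : "
      + " / ".join(f"{100 * f:.1f}%" for f in census.as_tuple()))
print()
print("Transcript levels are stationary within one episode (~8 min) while")
print("protein keeps accumulating for many hours (see the methods note);")
print("the census shows the permanent induction heterogeneity of the tank.")
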