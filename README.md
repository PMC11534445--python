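# scavsim

A trophic-web ODE simulator for studying how human hunting strategies and
the presence of wolves and wild boar shape the population dynamics of
European facultative scavengers (corvids, foxes, badgers, martens, …).

Ungulates are the main carrion source in European temperate ecosystems.
Where wolves are absent, hunting leftovers dominate the carrion supply;
where wolves return, partially consumed kills add a second channel. Wild
boar complicate the picture: they are prey, competitor and scavenger at
once. `scavsim` simulates the biomass of this web under configurable
hunting regimes and presence/absence of boar and wolf, and bookkeeps every
carrion flux so you can ask *where* scavenger growth actually comes from.

## The model

Five biomass densities (ton ha⁻¹, time in years): vegetation $V$, deer
$D$, boar $B$, facultative scavengers $S$, wolf $W$:

$$
\begin{aligned}
\dot V &= R_0 V (1 - V/k_0) - V^{cons}_D - V^{cons}_B - V^{cons}_S \\
\dot D &= D^{growth}_V - D^{pred} - D^{hunt} - D^{death} \\
\dot B &= B^{growth}_V + B^{growth}_D - B^{pred} - B^{hunt} - B^{death} \\
\dot S &= S^{growth}_V + S^{growth}_D + S^{growth}_B - M_S S \\
\dot W &= W^{growth}_D + W^{growth}_B - M_W W
\end{aligned}
$$

Key structural features:

* **Holling type-II consumption** throughout, with one shared
  half-saturation density $B_{XX}$.
* **Carrion as a flux, not a stock**: the deer pool
  $K_D = D^{death} + D^{hunt} L_D + D^{pred} v$ (boar analogously)
  collects natural mortality, the fraction $L$ of hunted biomass left in
  the field, and the fraction $v$ of wolf kills not consumed.
* **Boar scavenge first**: a saturating diet response sets the realized
  carrion portion $\ddot u < u$ of the boar diet, shrinks boar intake as
  carrion (which converts better than vegetation) increases, and only the
  residual deer carrion reaches the scavenger guild, whose carrion uptake
  is capped at availability (type-I).
* **Quota hunting**: no hunting below the target $T$; above it the flux is
  $H\,(X-T)^2/X$, so efficiency declines as density approaches the target.
* **Squared prey preference**: wolf offtake splits as $D^2 : B^2$, and the
  same weights suppress natural prey mortality
  ($e^{-qW\,X^2/(D^2+B^2)} M X$) — wolves take the old and weak first.

Absence of a guild is encoded by a zero initial biomass; the dynamics then
never create it. Integration uses a stiffness-switching adaptive solver
(LSODA) with an extinction floor applied on the output grid.

## Worked example

```python
import scavsim as sv

params = sv.ParameterSet()            # calibrated defaults
scenario = sv.ScenarioConfig()        # boar + wolf present, T=0.5, H=1, L=0.5
traj = sv.run_scenarios([scenario], params)[0]
print(sv.equilibrium_summary(traj, window=50).round(4))
```

```
     mean  amplitude
V  3.5017     0.0004
D  0.1505     0.0001
B  0.7204     0.0002
S  0.8343     0.0001
W  0.0131     0.0000
```

Over the last 50 of 250 simulated years the web sits at a near-point
equilibrium (amplitudes ≈ 0): vegetation grazed down to 3.5 ton ha⁻¹,
boar outweighing deer roughly 5:1, a scavenger guild of 0.83 ton ha⁻¹ and
a small persistent wolf population. The flux bookkeeping says what feeds
the scavengers:

```python
frac = sv.growth_source_series(traj)
origin = sv.carrion_origin_series(traj, sv.scenarios.apply_scenario(params, scenario))
```

At year 250 the vegetation share of scavenger growth is **0.925** — carrion
is a side dish — and the 0.136 ton ha⁻¹ yr⁻¹ carrion flux splits into
hunting 0.034, predation 0.032 and natural mortality 0.070.

## Command line

```bash
scavsim run --config my_run.yaml      # scenario grid -> CSVs, figures, metadata
scavsim run --dry-run                 # print the resolved grid
scavsim sensitivity --config my_run.yaml
scavsim check                         # structural invariant smoke test
```

A commented default configuration ships with the package
(`scavsim.cli.default_config_text()`); every run bundle echoes its fully
resolved configuration, and the whole pipeline is deterministic.

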