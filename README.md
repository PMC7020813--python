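# ecoaf

Information-theoretic condition metrics for ecosystem dynamics: a toolkit
for probing stability, regime shifts, recovery and antifragility in
multivariate environmental time series and flow networks.

## What it computes

- **Windowed Fisher information** of a phase-space trajectory
  (`ecoaf.fisher`): tangential speed/acceleration from a non-uniform
  three-point stencil, `I = (1/T) ∫ s″²/s′⁴ dt` per window, plus a
  baseline-band detector for post-disturbance recovery of the indicator.
- **Emergence / self-organization / complexity** (`ecoaf.complexity`):
  normalized Shannon information `E`, `S = 1 − E`, `C = 4·E·S`, from
  discrete distributions, binary sequences, or Bandt–Pompe ordinal
  patterns (permutation entropy); plus the `1/f^β` spectral exponent with
  white/pink/brown archetype classification.
- **Antifragility** (`ecoaf.antifragility`): the fragility functional
  `−ΔC·|Δx|` with fragile/robust/antifragile classification, Jensen-gap
  and scale-response convexity detectors for payoff functions, a
  replicated perturbation experiment on random Boolean networks, and a
  skewness-based homeostasis profile.
- **Ascendancy** (`ecoaf.ascendancy`): average mutual information of an
  inter-compartment flow matrix, with entropy capacity and overhead.
- **Spectral recovery** (`ecoaf.recovery`): NDMI, seasonal harmonic
  regression baselines, multi-band Euclidean deviation, and the time for
  deviations to return below a pre-disturbance quantile threshold.
- **Synthetic generators** (`ecoaf.synthetic`): seeded seasonal series
  with an abrupt disturbance and configurable partial/full recovery
  (a monthly vegetation-index analogue), `1/f^β` colored noise, random
  Boolean networks, and flow-network fixtures with known information
  content.
- **Preprocessing** (`ecoaf.core_io`): CSV time-series I/O with explicit
  gap masks, interpolation, min-max/z-score normalization, and the
  autocorrelation characteristic time τ₀.

## CLI

One entry point, `ecoaf`, with offline, deterministic subcommands. Each
run prints a JSON result line and can write a full report (tool version,
parameter echo, input digest):

```sh
# simulate a disturbed seasonal series and analyze it
ecoaf simulate ndvi --n 216 --disturbance 60 --drop 0.5 --rate 0.15 \
    --offset 0.1 --seed 11 --out ndvi.csv
ecoaf fisher --input ndvi.csv --window 12 --eps q50 --baseline 6:59 \
    --disturbance 60 --out fisher.csv --report report.json

# complexity and criticality of one variable
ecoaf complexity --input ndvi.csv --var NDVI --order 4 --out triple.json
ecoaf spectrum --input ndvi.csv --var NDVI --out beta.json

# antifragility
ecoaf antifragile rbn --N 20 --K 1,2,5 --X 1 --O 1 --T 200 --reps 100 \
    --seed 7 --out rbn.json
ecoaf antifragile payoff --expr "x**2" --sigmas 1,2,4 --n 10000 --seed 7

# flow networks
ecoaf simulate flows --n 4 --structure diagonal --out flows.csv
ecoaf ascendancy --input flows.csv

# harmonic-baseline recovery on multi-band input
ecoaf recovery --input bands.csv --bands NIR,SWIR1 --freq 12 \
    --harmonics 3 --disturbance 24 --baseline 0:24 --out recovery.json
```

A YAML file passed as `ecoaf --config cfg.yaml <subcommand> …` supplies
per-subcommand defaults; explicit flags win. Exit codes: 0 success,
1 user error, 2 internal failure.

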