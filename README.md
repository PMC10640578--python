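# burstnet

Construct discrete-time temporal networks in which every node and every
link switches between active and inactive states so that their
inter-event-time (IET) distributions match prescribed targets — bursty
(discrete power law) or Poisson-like (discrete exponential) — on static,
growing, or rewiring underlying topologies.

The method couples binary renewal processes through a spanning tree:
nodes and tree edges ("trunks") are driven jointly, root outward, by
their exact discrete hazards; every off-tree edge ("branch") is active
precisely when both of its endpoints are. A pair of target laws is
*consistent* when the four joint next-step probabilities of every
two-node system stay in [0, 1] on all reachable trajectories; the
package ships both closed-form consistency conditions and an exhaustive
numeric checker, plus the statistical machinery (discrete MLE fits,
burstiness, autocorrelation, time-aggregated strength analysis) used to
validate constructions.

## Layout

| module | contents |
| --- | --- |
| `burstnet.distributions` | discrete waiting-time laws: pmf / survival / hazard, closed-form first-activation probabilities |
| `burstnet.two_node` | coupled two-node systems, joint step probabilities, exact trajectory enumeration, consistency checking |
| `burstnet.construction` | spanning trees (Wilson / BFS), layer-wise tree simulator, static-topology construction |
| `burstnet.dynamic` | temporal preferential-attachment model, general time-varying-topology driver with spanning-tree repair |
| `burstnet.analysis` | IET/ICT extraction, power-law and exponential MLEs (incl. finite-window correction), burstiness, aggregation |
| `burstnet.io`, `burstnet.topologies`, `burstnet.cli` | contact-triplet formats, fixture topologies, command line |

## Quick start

```python
import burstnet as bn

t_tol = 10_000
L = bn.distributions.default_support(t_tol)
F = bn.make_distribution("power_law", 2.0, L)   # node target
H = bn.make_distribution("power_law", 1.9, L)   # trunk target

bn.check_consistency(F, F, H, mode="bursty_analytic")   # -> consistent

g = bn.generate_fixture_topology("ba", {"n": 1000, "m": 3}, seed=1)
net = bn.construct_static(g, F, H, t_tol, seed=2)

gaps = bn.extract_intervals(net, "node_iet", scope="aggregated")
bn.fit_discrete_power_law(gaps, window=t_tol).exponent_hat  # ~2.00
```

## CLI

```sh
burstnet generate  -c config.yaml -d out/      # construct + write contacts
burstnet check     -c config.yaml              # consistency verdict (exit code)
burstnet analyze   out/contacts.tsv -o report  # ICT/IET fits + burstiness
burstnet aggregate out/contacts.tsv --t-agg 5000 --t-base 1000 -o strengths.tsv
```

Config example:

```yaml
topology: {family: ws, params: {n: 1000, k: 6, p: 0.1}}
targets:
  nodes:  {kind: power_law, exponent: 2.0}
  trunks: {kind: power_law, exponent: 1.9}
run: {t_tol: 10000, seed: 1}
outputs: {contacts: contacts.tsv}
```

Contact files are whitespace-separated `t i j` triplets (the reader also
accepts SocioPatterns-style files with extra metadata columns; raw
timestamps are compressed to consecutive steps).

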