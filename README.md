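# hemonet

Closed-loop 1D arterial–venous pulse-wave simulation with lumped heart,
coronary and intracranial-pressure coupling.

`hemonet` is for computational physiologists who want to simulate blood
pressure and flow waveforms through a *closed* circulation: 1D compliant
vessels for systemic arteries and veins, coupled to 0D models of the four
heart chambers (time-varying elastance with septal and pericardial
interaction), the cardiac and venous valves, the pulmonary circulation,
peripheral and coronary microcirculation beds, Starling resistors at the
cerebral-vein/dural-sinus interface, and the intracranial-pressure (ICP)
compliance. The venous side matters here: veins follow a collapsible-tube
law, venous return can choke, cerebral outflow shows the vascular-waterfall
effect, and coronary flow is squeezed by the intramyocardial pump.

## Model core

Per vessel, the 1D blood-flow equations

    A_t + q_x = 0
    q_t + (q²/A)_x + (A/ρ) p_x = −8πμ q/(ρA)

are closed by distinct tube laws: arteries use an elastin+collagen mixture
law p_tm = (πR₀h₀/A)[E_e ε + E_c ε_r ln(e^χ + 1)] + Γ A_t + p₀; veins use
the collapsible law p_tm = K[(A/A₀)^m − (A/A₀)^n] + Γ A_t + p₀ with
(m, n) = (10, −3/2) (dural sinuses (1/2, 0)). Wall parameters derive from
the radius alone (radius groups + mixture weights for arteries, a
celerity–radius rule K = ρc²/(m−n) for veins). The discretization is a
second-order, well-balanced, path-conservative finite-volume scheme with a
relaxation variable for the viscoelastic rate term, local time stepping
synchronized at junctions, and Newton-solved coupling conditions
(Riemann invariants + mass + total-pressure continuity) at every junction
and 1D–0D interface. Details and all deliberate modelling choices are in
[docs/methods.md](docs/methods.md).

Networks are plain CSV tables (one row per vessel: connectivity, length,
end radii, class, terminal parameters, arterio-venous targets); two
built-in closed-loop fixture generators (`minimal`, `cerebral_coronary`)
exercise every component with no external data.

## Worked example

```python
import hemonet as hn

net = hn.build_fixture_network("minimal", seed=1)
probe = hn.assemble(net, hn.SimulationConfig(V_set=None))
cfg = hn.SimulationConfig(V_set=probe.V_stretched0 + 30.0)  # stressed-volume set point
sim = hn.assemble(net, cfg)
rec = sim.run(n_cycles=20)            # stops when cycles become periodic

battery = hn.compute_indexes(rec, hn.analysis.SiteSpec(aorta="v1:ascending aorta"))
print(f"MAP {battery.in_mmhg('MAP'):.1f} mmHg, "
      f"SBP/DBP {battery.in_mmhg('SBP'):.0f}/{battery.in_mmhg('DBP'):.0f}, "
      f"CO {battery['CO']:.1f} mL/s, LVEF {100*battery['LVEF']:.0f}%")
```

prints (seed 1):

```
MAP 90.2 mmHg, SBP/DBP 128/58, CO 86.9 mL/s, LVEF 60%
```

i.e. the 4-vessel closed loop settles to a mean aortic pressure of
90 mmHg, a 128/58 mmHg aortic waveform, a cardiac output of 87 mL/s and a
left-ventricular ejection fraction of 60% — a coherent adult operating
point produced entirely by the interaction of the elastance heart, the
1D vessels and the derived peripheral parameters. After the 3-second
enforcement phase the total stressed volume matches the configured set
point to 0.002%, and total blood volume drifts by ~1e-4 % per cycle.
The `cerebral_coronary` fixture adds the brain and heart circuits: on it
the model yields a cerebral blood flow of ~7 mL/s, a coronary flow of
~2.4 mL/s with the classic diastolic-dominant pattern, and a collapsed
Starling resistor operating as a vascular waterfall (cerebral outflow
insensitive to sinus pressure below the ICP). Fixture-scale equilibria
are self-consistent but not population-comparable; see the methods note.

A command-line layer mirrors the library:

```
hemonet fixture --size cerebral_coronary --seed 1 --out net.csv
hemonet validate net.csv --elements net.elements.csv
hemonet run --network net.csv --elements net.elements.csv --cycles 8 --out out.h5
hemonet probe out.h5 --vessel 1 --quantity pressure --units mmHg
hemonet indexes out.h5 --aorta "v1:ascending aorta"
hemonet sensitivity --network net.csv --elements net.elements.csv \
        --params R_per,C_v_data,V_set --out table.csv
```

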