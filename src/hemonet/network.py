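"""Vessel-network data model, CSV reader/writer, validation and fixtures.

A network is a directed multigraph of 1D vessel segments (each with a local
axis running proximal -> distal) plus:

* junction specs (which vessel ends meet at each shared node, with
  orientation flags g_k = +1 for a distal/outlet end, -1 for a proximal end);
* interposed lumped elements (venous valves, Starling resistors) that replace
  a two-vessel junction;
* terminal-artery specs (total peripheral resistance and residual arterial
  compliance) and the bipartite arterio-venous connectivity that wires
  terminal arteries to the terminal veins draining the same territory;
* heart attachment points (aortic root inlet; SVC/IVC/coronary-sinus outlets
  into the right atrium).

File format: one CSV row per vessel with the columns of ``VESSEL_COLUMNS``;
interposed elements in a second CSV (kind, vessel_up, vessel_down). A
column-name mapping can adapt externally produced tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd


class VesselClass(str, Enum):
    ARTERY = "artery"
    PERFORATOR = "perforator"
    VEIN = "vein"
    DURAL_SINUS = "dural_sinus"


ARTERIAL_CLASSES = (VesselClass.ARTERY, VesselClass.PERFORATOR)
VENOUS_CLASSES = (VesselClass.VEIN, VesselClass.DURAL_SINUS)


class ElementKind(str, Enum):
    VENOUS_VALVE = "venous_valve"
    STARLING_RESISTOR = "starling_resistor"
    CARDIAC_VALVE_SITE = "cardiac_valve_site"


@dataclass
class Vessel:
    id: int
    name: str
    node_prox: int
    node_dist: int
    length: float          # cm
    radius_prox: float     # cm
    radius_dist: float     # cm
    vessel_class: VesselClass
    region_id: int = 0
    terminal_artery: bool = False
    terminal_vein: bool = False
    intracranial: bool = False

    def __post_init__(self):
        self.vessel_class = VesselClass(self.vessel_class)
        if self.length <= 0:
            raise ValueError(f"vessel {self.id}: non-positive length")
        if self.radius_prox <= 0 or self.radius_dist <= 0:
            raise ValueError(f"vessel {self.id}: non-positive radius")
        if self.node_prox == self.node_dist:
            raise ValueError(f"vessel {self.id}: self-loop")
        if self.terminal_artery and self.vessel_class not in ARTERIAL_CLASSES:
            raise ValueError(f"vessel {self.id}: terminal_artery on non-arterial class")
        if self.terminal_vein and self.vessel_class not in VENOUS_CLASSES:
            raise ValueError(f"vessel {self.id}: terminal_vein on non-venous class")

    @property
    def is_arterial(self) -> bool:
        return self.vessel_class in ARTERIAL_CLASSES

    def radius_at(self, s):
        """Linearly tapered radius at fractional axial position s in [0, 1]."""
        s = np.asarray(s, dtype=float)
        return self.radius_prox + (self.radius_dist - self.radius_prox) * s


@dataclass
class JunctionSpec:
    node: int
    members: list  # list of (vessel_id, g) with g=+1 when the distal end meets the node


@dataclass
class InterposedElementSpec:
    kind: ElementKind
    vessel_up: int
    vessel_down: int

    def __post_init__(self):
        self.kind = ElementKind(self.kind)


@dataclass
class TerminalArterySpec:
    vessel: int
    R_t: float             # dyn s/cm^5
    C_a: float             # cm^5/dyn
    territory: str = ""
    draining_veins: list = field(default_factory=list)

    def __post_init__(self):
        if self.R_t <= 0 or self.C_a <= 0:
            raise ValueError(f"terminal artery {self.vessel}: R_t and C_a must be positive")


@dataclass
class AVConnectivity:
    """Bipartite terminal-artery / terminal-vein edge set with resistances."""

    edges: dict = field(default_factory=dict)  # (artery_id, vein_id) -> R or None

    def arteries(self):
        return sorted({a for a, _ in self.edges})

    def veins(self):
        return sorted({v for _, v in self.edges})

    def veins_of(self, artery_id):
        return sorted(v for a, v in self.edges if a == artery_id)

    def arteries_of(self, vein_id):
        return sorted(a for a, v in self.edges if v == vein_id)


@dataclass
class HeartAttachment:
    aortic_root_vessel: int
    atrial_inlet_vessels: list        # SVC/IVC vessel ids draining to the RA
    coronary_sinus_vessel: int | None = None


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self):
        if self.ok:
            return "OK: no invariant violations"
        return "\n".join(f"- {v}" for v in self.violations)


@dataclass
class NetworkTopology:
    vessels: dict                       # id -> Vessel
    junctions: list                     # [JunctionSpec]
    elements: list                      # [InterposedElementSpec]
    terminals: dict                     # artery id -> TerminalArterySpec
    av: AVConnectivity
    heart: HeartAttachment
    coronary_walls: dict = field(default_factory=dict)  # terminal artery id -> wall name

    def vessels_by_class(self):
        counts = {c: 0 for c in VesselClass}
        for v in self.vessels.values():
            counts[v.vessel_class] += 1
        return counts

    def terminal_veins(self):
        return sorted(v.id for v in self.vessels.values() if v.terminal_vein)

    def element_at(self, vessel_up, vessel_down):
        for e in self.elements:
            if e.vessel_up == vessel_up and e.vessel_down == vessel_down:
                return e
        return None


VESSEL_COLUMNS = [
    "id", "name", "class", "node_prox", "node_dist", "length_cm",
    "radius_prox_cm", "radius_dist_cm", "region_id", "terminal_artery",
    "terminal_vein", "Rt_dyn_s_cm5", "Ca_cm5_dyn", "territory", "av_targets",
]
OPTIONAL_COLUMNS = ["intracranial", "coronary_wall", "x_prox", "y_prox",
                    "z_prox", "x_dist", "y_dist", "z_dist"]
ELEMENT_COLUMNS = ["kind", "vessel_up", "vessel_down"]


def _build_junctions(vessels: dict, element_pairs: set) -> list:
    """Derive junction specs from shared nodes, skipping nodes occupied by an
    interposed element (valve/Starling resistor) and boundary nodes."""
    node_members: dict[int, list] = {}
    for v in vessels.values():
        node_members.setdefault(v.node_prox, []).append((v.id, -1))
        node_members.setdefault(v.node_dist, []).append((v.id, +1))
    element_nodes = set()
    for up, down in element_pairs:
        vu, vd = vessels[up], vessels[down]
        shared = {vu.node_dist} & {vd.node_prox}
        if not shared:
            raise ValueError(
                f"interposed element {up}->{down}: vessels do not share "
                "an up-distal/down-proximal node")
        element_nodes |= shared
    out = []
    for node, members in sorted(node_members.items()):
        if node in element_nodes or len(members) < 2:
            continue
        out.append(JunctionSpec(node=node, members=sorted(members)))
    return out


def _parse_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in ("1", "true", "yes", "y")
    return bool(int(x)) if not pd.isna(x) else False


def load_network(path, elements_path=None, column_map: dict | None = None,
                 heart: HeartAttachment | None = None) -> NetworkTopology:
    """Read a vessel table (and optional elements table) into a topology.

    ``column_map`` maps this package's canonical column names to the names
    used in the file, so externally produced tables can be adapted without
    editing them.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in VESSEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")

    vessels, terminals, av = {}, {}, AVConnectivity()
    coronary_walls = {}
    for _, row in df.iterrows():
        vid = int(row["id"])
        v = Vessel(
            id=vid, name=str(row["name"]),
            node_prox=int(row["node_prox"]), node_dist=int(row["node_dist"]),
            length=float(row["length_cm"]),
            radius_prox=float(row["radius_prox_cm"]),
            radius_dist=float(row["radius_dist_cm"]),
            vessel_class=VesselClass(str(row["class"])),
            region_id=int(row.get("region_id", 0) or 0),
            terminal_artery=_parse_bool(row["terminal_artery"]),
            terminal_vein=_parse_bool(row["terminal_vein"]),
            intracranial=_parse_bool(row["intracranial"]) if "intracranial" in df.columns else False,
        )
        vessels[vid] = v
        if v.terminal_artery:
            targets = [int(float(t)) for t in str(row["av_targets"]).split(";")
                       if t.strip() and t.strip().lower() != "nan"]
            if not targets:
                raise ValueError(f"vessel {vid}: terminal artery with no draining vein")
            spec = TerminalArterySpec(
                vessel=vid, R_t=float(row["Rt_dyn_s_cm5"]),
                C_a=float(row["Ca_cm5_dyn"]),
                territory=str(row.get("territory", "") or ""),
                draining_veins=targets)
            terminals[vid] = spec
            for t in targets:
                av.edges[(vid, t)] = None
            if "coronary_wall" in df.columns and isinstance(row.get("coronary_wall"), str) \
                    and row["coronary_wall"].strip():
                coronary_walls[vid] = row["coronary_wall"].strip()

    elements = []
    if elements_path is not None and Path(elements_path).exists():
        edf = pd.read_csv(elements_path)
        for _, row in edf.iterrows():
            elements.append(InterposedElementSpec(
                kind=ElementKind(str(row["kind"])),
                vessel_up=int(row["vessel_up"]), vessel_down=int(row["vessel_down"])))

    junctions = _build_junctions(vessels, {(e.vessel_up, e.vessel_down) for e in elements})
    if heart is None:
        heart = _infer_heart_attachment(vessels, junctions, elements)
    net = NetworkTopology(vessels=vessels, junctions=junctions, elements=elements,
                          terminals=terminals, av=av, heart=heart,
                          coronary_walls=coronary_walls)
    report = validate_topology(net)
    errors = [v for v in report.violations if "warning" not in v]
    if errors:
        raise ValueError("invalid network:\n" + "\n".join(errors))
    return net


def save_network(net: NetworkTopology, path, elements_path=None):
    """Write the topology back to the CSV dialect (round-trips load_network)."""
    rows = []
    for v in sorted(net.vessels.values(), key=lambda x: x.id):
        spec = net.terminals.get(v.id)
        rows.append({
            "id": v.id, "name": v.name, "class": v.vessel_class.value,
            "node_prox": v.node_prox, "node_dist": v.node_dist,
            "length_cm": repr(v.length),
            "radius_prox_cm": repr(v.radius_prox),
            "radius_dist_cm": repr(v.radius_dist),
            "region_id": v.region_id,
            "terminal_artery": int(v.terminal_artery),
            "terminal_vein": int(v.terminal_vein),
            "Rt_dyn_s_cm5": repr(spec.R_t) if spec else "",
            "Ca_cm5_dyn": repr(spec.C_a) if spec else "",
            "territory": spec.territory if spec else "",
            "av_targets": ";".join(str(t) for t in spec.draining_veins) if spec else "",
            "intracranial": int(v.intracranial),
            "coronary_wall": net.coronary_walls.get(v.id, ""),
        })
    pd.DataFrame(rows).to_csv(path, index=False)
    if elements_path is not None:
        pd.DataFrame([{"kind": e.kind.value, "vessel_up": e.vessel_up,
                       "vessel_down": e.vessel_down} for e in net.elements],
                     columns=ELEMENT_COLUMNS).to_csv(elements_path, index=False)


def _infer_heart_attachment(vessels, junctions, elements):
    """Boundary ends: arterial proximal end with no junction -> aortic root;
    venous distal ends with no junction -> atrial inlets."""
    junction_nodes = {j.node for j in junctions}
    element_nodes = set()
    for e in elements:
        element_nodes.add(vessels[e.vessel_up].node_dist)
    root, inlets, cs = None, [], None
    for v in vessels.values():
        if v.is_arterial and v.node_prox not in junction_nodes | element_nodes:
            prox_shared = any(o.id != v.id and v.node_prox in (o.node_prox, o.node_dist)
                              for o in vessels.values())
            if not prox_shared:
                root = v.id
        if not v.is_arterial and v.node_dist not in junction_nodes | element_nodes:
            dist_shared = any(o.id != v.id and v.node_dist in (o.node_prox, o.node_dist)
                              for o in vessels.values())
            if not dist_shared:
                inlets.append(v.id)
    # coronary sinus: a venous inlet in a coronary region (name hint)
    for vid in list(inlets):
        if "coronary" in vessels[vid].name.lower() or "cardiac" in vessels[vid].name.lower():
            cs = vid
            inlets.remove(vid)
    return HeartAttachment(aortic_root_vessel=root, atrial_inlet_vessels=sorted(inlets),
                           coronary_sinus_vessel=cs)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_topology(net: NetworkTopology) -> ValidationReport:
    """Check every structural invariant; returns a report, never raises."""
    rep = ValidationReport()
    add = rep.violations.append

    ids = set(net.vessels)
    for e in net.elements:
        if e.vessel_up not in ids or e.vessel_down not in ids:
            add(f"element {e.kind.value}: unknown vessel id")
            continue
        vu, vd = net.vessels[e.vessel_up], net.vessels[e.vessel_down]
        if e.kind is ElementKind.STARLING_RESISTOR:
            if vu.is_arterial or vd.is_arterial:
                add(f"starling_resistor {e.vessel_up}->{e.vessel_down}: "
                    "starling_resistor requires vein/dural_sinus pair")
        if e.kind is ElementKind.VENOUS_VALVE:
            if vu.is_arterial or vd.is_arterial:
                add(f"venous_valve {e.vessel_up}->{e.vessel_down}: requires venous pair")

    term_arteries = {v.id for v in net.vessels.values() if v.terminal_artery}
    term_veins = {v.id for v in net.vessels.values() if v.terminal_vein}
    for a in term_arteries:
        if not net.av.veins_of(a):
            add(f"terminal artery {a} without draining vein")
    for v in term_veins:
        if not net.av.arteries_of(v):
            add(f"terminal vein {v} without arterial feeder")
    for (a, v) in net.av.edges:
        if a not in term_arteries:
            add(f"AV edge ({a},{v}): {a} is not a terminal artery")
        if v not in term_veins:
            add(f"AV edge ({a},{v}): {v} is not a terminal vein")
    for a, spec in net.terminals.items():
        for t in spec.draining_veins:
            if t not in ids:
                add(f"terminal artery {a}: unknown draining vein {t}")

    # closed-loop reachability through the lumped heart: every arterial vessel
    # reachable downstream from the aortic root; every venous vessel reaches
    # an atrial inlet. AV edges bridge terminal arteries to terminal veins.
    succ: dict[int, set] = {i: set() for i in ids}
    for j in net.junctions:
        outs = [vid for vid, g in j.members if g == +1]   # flow arrives
        ins = [vid for vid, g in j.members if g == -1]    # flow departs
        for o in outs:
            succ[o].update(ins)
    for e in net.elements:
        succ[e.vessel_up].add(e.vessel_down)
    for (a, v) in net.av.edges:
        succ[a].add(v)

    if net.heart.aortic_root_vessel is None:
        add("no aortic-root vessel (arterial inlet) found")
    else:
        reached = set()
        stack = [net.heart.aortic_root_vessel]
        while stack:
            cur = stack.pop()
            if cur in reached:
                continue
            reached.add(cur)
            stack.extend(succ[cur] - reached)
        unreachable = ids - reached
        if unreachable:
            add(f"vessels unreachable from aortic root: {sorted(unreachable)}")
        sinks = set(net.heart.atrial_inlet_vessels)
        if net.heart.coronary_sinus_vessel is not None:
            sinks.add(net.heart.coronary_sinus_vessel)
        if not sinks:
            add("no venous inlet to the right atrium found")
        else:
            # reverse reachability to the atrial sinks
            pred: dict[int, set] = {i: set() for i in ids}
            for u, outs in succ.items():
                for w in outs:
                    pred[w].add(u)
            reaches = set()
            stack = list(sinks)
            while stack:
                cur = stack.pop()
                if cur in reaches:
                    continue
                reaches.add(cur)
                stack.extend(pred[cur] - reaches)
            stranded = ids - reaches
            if stranded:
                add(f"vessels that cannot reach the right atrium: {sorted(stranded)}")
    return rep


# ---------------------------------------------------------------------------
# Fixture networks
# ---------------------------------------------------------------------------

def _v(id, name, cls, np_, nd, L, rp, rd, **kw):
    return Vessel(id=id, name=name, vessel_class=cls, node_prox=np_, node_dist=nd,
                  length=L, radius_prox=rp, radius_dist=rd, **kw)


def build_fixture_network(size: str = "minimal", seed: int = 0) -> NetworkTopology:
    """Reduced closed-loop networks exercising every model component.

    ``minimal``: aortic root -> 2 arteries -> 1 peripheral bed -> 1 vein ->
    vena cava -> right atrium (4 1D vessels).

    ``cerebral_coronary``: 14 vessels with a bifurcating arterial tree, a
    cerebral branch (intracranial vein -> Starling resistor -> dural sinus ->
    jugular chain with one venous valve), a coronary artery/vein pair on a
    coronary bed, a three-vessel venous confluence, and the generic
    many-to-many arterio-venous pattern (one artery feeding two veins, one
    vein fed by two arteries). The seed perturbs radii (a few percent) but
    never the topology.
    """
    rng = np.random.default_rng(seed)

    def jig(r):
        # reproducible few-percent radius perturbation
        return float(r * (1.0 + 0.03 * rng.standard_normal()))

    if size == "minimal":
        A = VesselClass.ARTERY
        V = VesselClass.VEIN
        # calibers sized to carry the full cardiac output through a single
        # serial path (the fixture has no parallel branches to share it)
        vessels = {
            1: _v(1, "ascending aorta", A, 0, 1, 5.0, jig(1.25), jig(1.1)),
            2: _v(2, "systemic artery", A, 1, 2, 12.0, jig(0.9), jig(0.75),
                  terminal_artery=True),
            3: _v(3, "systemic vein", V, 3, 4, 12.0, jig(1.25), jig(1.35),
                  terminal_vein=True),
            4: _v(4, "vena cava", V, 4, 5, 6.0, jig(1.4), jig(1.55)),
        }
        df_terms = {2: TerminalArterySpec(vessel=2, R_t=1300.0, C_a=7.5e-4,
                                          territory="body", draining_veins=[3])}
        av = AVConnectivity(edges={(2, 3): None})
        elements: list = []
        heart = HeartAttachment(aortic_root_vessel=1, atrial_inlet_vessels=[4])
        junctions = _build_junctions(vessels, set())
        return NetworkTopology(vessels=vessels, junctions=junctions, elements=elements,
                               terminals=df_terms, av=av, heart=heart)

    if size == "cerebral_coronary":
        A, P = VesselClass.ARTERY, VesselClass.PERFORATOR
        V, D = VesselClass.VEIN, VesselClass.DURAL_SINUS
        vessels = {
            1: _v(1, "ascending aorta", A, 0, 1, 5.0, jig(1.25), jig(1.15)),
            2: _v(2, "cerebral artery", A, 1, 2, 15.0, jig(0.25), jig(0.16),
                  terminal_artery=True, intracranial=True, region_id=1),
            3: _v(3, "systemic artery a", A, 1, 3, 18.0, jig(0.55), jig(0.42),
                  terminal_artery=True, region_id=2),
            4: _v(4, "systemic artery b", A, 1, 4, 18.0, jig(0.55), jig(0.42),
                  terminal_artery=True, region_id=2),
            5: _v(5, "coronary artery", P, 1, 5, 6.0, jig(0.16), jig(0.1),
                  terminal_artery=True, region_id=3),
            6: _v(6, "cerebral vein", V, 6, 7, 4.0, jig(0.2), jig(0.25),
                  terminal_vein=True, intracranial=True, region_id=1),
            7: _v(7, "dural sinus", D, 7, 8, 5.0, jig(0.3), jig(0.35), region_id=1),
            8: _v(8, "jugular vein", V, 8, 9, 8.0, jig(0.4), jig(0.45), region_id=1),
            9: _v(9, "superior vena cava", V, 9, 10, 5.0, jig(0.7), jig(0.9),
                  region_id=1),
            10: _v(10, "systemic vein a", V, 11, 12, 14.0, jig(0.9), jig(1.0),
                   terminal_vein=True, region_id=2),
            11: _v(11, "systemic vein b", V, 13, 12, 14.0, jig(0.85), jig(0.95),
                   terminal_vein=True, region_id=2),
            12: _v(12, "inferior vena cava", V, 12, 14, 8.0, jig(1.3), jig(1.45),
                   region_id=2),
            13: _v(13, "cardiac vein", V, 15, 16, 4.0, jig(0.22), jig(0.28),
                   terminal_vein=True, region_id=3),
            14: _v(14, "coronary sinus", V, 16, 17, 3.0, jig(0.35), jig(0.42),
                   region_id=3),
        }
        terms = {
            2: TerminalArterySpec(vessel=2, R_t=9.7e3, C_a=9.0e-5,
                                  territory="cerebral", draining_veins=[6]),
            3: TerminalArterySpec(vessel=3, R_t=4.0e3, C_a=2.6e-4,
                                  territory="body-a", draining_veins=[10]),
            4: TerminalArterySpec(vessel=4, R_t=4.0e3, C_a=2.6e-4,
                                  territory="body-b", draining_veins=[10, 11]),
            5: TerminalArterySpec(vessel=5, R_t=2.6e4, C_a=3.5e-5,
                                  territory="coronary", draining_veins=[13]),
        }
        av = AVConnectivity(edges={(2, 6): None, (3, 10): None, (4, 10): None,
                                   (4, 11): None, (5, 13): None})
        elements = [
            InterposedElementSpec(kind=ElementKind.STARLING_RESISTOR,
                                  vessel_up=6, vessel_down=7),
            InterposedElementSpec(kind=ElementKind.VENOUS_VALVE,
                                  vessel_up=8, vessel_down=9),
        ]
        heart = HeartAttachment(aortic_root_vessel=1, atrial_inlet_vessels=[9, 12],
                                coronary_sinus_vessel=14)
        junctions = _build_junctions(vessels, {(e.vessel_up, e.vessel_down)
                                               for e in elements})
        return NetworkTopology(vessels=vessels, junctions=junctions,
                               elements=elements, terminals=terms, av=av,
                               heart=heart, coronary_walls={5: "LV-fw"})

    raise ValueError(f"unknown fixture size {size!r}")
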