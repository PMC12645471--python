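# haloscope

In-silico discovery and substrate-scope prediction for flavin-dependent
halogenases (FDHs).

FDHs generate hypohalous acid (HOX) at a FAD cofactor, steer it down a
~10 Å tunnel to a conserved catalytic lysine, and halogenate an aromatic
C–H position of a bound substrate with a regioselectivity set by how the
pocket presents the ring to that lysine. `haloscope` implements the
computational half of an FDH engineering campaign as a tested, reusable
pipeline:

1. **Genome mining** — degenerate-motif screening of protein FASTA for
   the three FDH signature motifs (`GxGxxG`, `WxWxIP`, `Fx.Px.SxG`,
   required in N→C order), plus neighbor-joining phylogenetic placement
   with column-bootstrap supports.
2. **Pocket mapping** — LIGSITE-style grid scanning of a predicted
   receptor structure for interior cavities, clearance-weighted Dijkstra
   search for the HOX tunnel, and triage of candidate pockets by lysine
   proximity, tunnel connectivity, and (optionally) docking evidence.
3. **Pose geometry** — parsing of docked ligand poses (Vina-dialect
   PDBQT or multi-model PDB + energy table), identification of the
   predicted halogenation carbon (the eligible aromatic C–H nearest the
   K79 reference), and its distances to the K79/D307 catalytic pair.
4. **Substrate classification** — the decision rule

   - binding energy *E* in the optimal window
     −35.56 kJ/mol ≤ *E* ≤ −20.92 kJ/mol (= −8.5 … −5.0 kcal/mol;
     weaker binders are non-binders, much tighter ones risk poor
     turnover; a 1 kJ/mol `borderline_tight` band past the tight bound
     is accepted by default), and
   - d(C···D307) ≤ 11.5 Å for the carbon to be activated,

   with regiochemistry read off the retained near-degenerate poses:
   one retained orientation → single regioselective product, two →
   a regioisomer mixture, and a site whose molecular-graph symmetry
   class has ≥ 2 members → one product from equivalent positions
   ("symmetric" halogenation).

Docking engines and structure predictors are consumed, not implemented:
the pipeline starts from sequences, structures, and pose files.

## Worked example

Two near-degenerate binding orientations of 2-(isoxazol-5-yl)phenol,
2.10 kJ/mol apart at distinct ring positions:

```python
import numpy as np
from haloscope import (parse_ligand, eligible_sites, assign_site,
                       classify_candidate, classify_energy,
                       predict_regiochemistry)
from haloscope.synthetic import gen_pose_set

topo = parse_ligand("Oc1ccccc1-c1ccno1")        # 2-(isoxazol-5-yl)phenol
sites = eligible_sites(topo)

k79, d307 = np.zeros(3), np.array([6.0, 0.0, 0.0])
poses, _ = gen_pose_set(topo, [sites[0], sites[1]], [-24.69, -22.59],
                        [10.2, 8.5], [9.0, 9.5], k79, d307, seed=0,
                        compound_id="cmpd7")
pwa = [(p, assign_site(p, topo, k79, d307)) for p in poses]
for p, a in pwa:
    print(f"pose {p.pose_id}: E = {p.binding_energy:.2f} kJ/mol "
          f"({classify_energy(p.binding_energy)}), site atom {a.site_atom_index}, "
          f"d(K79) = {a.d_k79:.1f} A, d(D307) = {a.d_d307:.1f} A")

call = classify_candidate("cmpd7", pwa, topo)
print("verdict:", call.label, "| predicted sites:", len(call.predicted_sites))
```

prints

```
pose 1: E = -24.69 kJ/mol (optimal), site atom 2, d(K79) = 10.2 A, d(D307) = 9.0 A
pose 2: E = -22.59 kJ/mol (optimal), site atom 3, d(K79) = 8.5 A, d(D307) = 9.5 A
verdict: substrate | predicted sites: 2
```

Both orientations fall in the optimal window and within the 11.5 Å
D307 gate, and they sit at different symmetry classes, so the compound
is called a substrate with **two predicted regioisomers** — the
orientation closer to K79 (8.5 Å vs 10.2 Å) is the one positioned for
a follow-up second halogenation.

## Command line

```
haloscope mine   --fasta seqs.fasta --out hits.tsv
haloscope tree   --fasta aligned.fasta --bootstrap 100 --seed 1 --out tree.nwk
haloscope pockets --pdb model.pdb --out pockets.json
haloscope tunnel  --pdb model.pdb --start A/79/NZ --pocket 0
haloscope simulate screen --n 53 --substrates 7 --seed 1 --outdir fixture/
haloscope classify --fixture fixture/ --out calls.json
haloscope run    --config config.json --outdir run/
```

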