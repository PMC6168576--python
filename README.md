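# pachyshell

Lattice-spring shell mechanics for the cracking of a brittle, growing
stratum corneum on papillated skin — the mechanism behind the
micrometre-width channel network of African elephant skin — together with
the tri-junction angular statistics used to tell crack networks from
trough (valley-line) networks.

## Who this is for

Researchers in tissue biomechanics and pattern formation who want a small,
fully scriptable model of thin-shell fracture on structured substrates:
simulate growth- or desiccation-driven cracking on synthetic (or imported)
papillated geometries, and quantify the resulting 2D crack networks the
way skin-pattern studies do.

## The model

The outer stratum corneum is a thin brittle **shell**: a sheet whose
stress-free state is curved, because it formed on a dermal surface covered
by millimetric papillae and its dead keratinised cells cannot rearrange.
On a triangle mesh with positions `x`, rest lengths `l0` and rest dihedral
angles `θ0` (frozen at initialisation), the energy is

```
E = Σ_edges (k_s/2) l0 ε²  +  Σ_hinges k_b (θ − θ0)²  +  Σ_faces (k_v/2) A0 (A/A0 − 1)²
  + Σ_nodes (k_sub/2) |x − (p + h n)|²  +  Σ_nodes (k_pen/2) max(0, S(x,y) − z)²
  + Σ_pairs (k_c/2) (d_c − d)²
```

— springs, bending hinges, area preservation, a tether to the substrate
surface offset by the growth amount `h` along frozen normals, a one-sided
penalty keeping the sheet above the solid dermis `S`, and node-face
self-contact.  Loading is quasi-static: increment `h` (growth) or shrink
the rest metric uniformly (desiccation), relax by damped Newtonian
dynamics, then break one bond at a time wherever the fibre strain

```
ε_eff = ε_membrane − (t_s/2)(κ − κ0),   κ = 2θ/(h1 + h2)
```

exceeds the critical strain `ε_c` (re-relaxing after every break).  Growth
pinches the troughs between papillae and breaks trough bonds by bending;
desiccation puts the sheet under tension that the troughs partially escape
by lifting off, so its cracks run across the troughs and over the papillae
— the two protocols produce geometrically opposite crack networks on the
same substrate.

Crack networks are projected to the plane and characterised by their
tri-junctions: each junction's sorted angles `θ1 ≤ θ2 ≤ θ3` (summing to
360°) give a point `(θ1, θ2)`; a population is summarised by its mean
point, its angular spreading `σθ = sqrt(A_1σ/π)` (the 68%-mass Gaussian
error ellipse area `A_1σ`), and nearest-archetype counts among triple-120°,
90°–135°–135° and T-junction.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

`examples/growth_cracking.py` grows a shell on sinusoidal ridges until 2%
of its bonds have failed:

```
$ python examples/growth_cracking.py
final growth offset h = 0.250 mm (= spacing/6 at most)
broken edges: 18 (2.016% of all edges)
fraction of breaks inside the trough bands: 1.00
```

Every broken edge lies in the valley bands between the ridges: growth on a
curved substrate concentrates bending strain — and hence fracture — in the
troughs, which is exactly where the elephant's skin channels sit.  The
other scripts in `examples/` generate papillated substrates, contrast
growth with desiccation on an identical substrate, compute trough-network
junction statistics and cut virtual cross-sections through a cracked
shell.

A thin CLI wraps the same library calls:

```
pachyshell generate-substrate --seed 1 --out out/
pachyshell simulate --protocol growth --seed 1 --out out/
pachyshell compare --seed 1 --out out/
```

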