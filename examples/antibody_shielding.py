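"""Demonstrate packing-dependent antibody shielding (random sequential adsorption).

Sweeps the intra-cluster molecule count at fixed cluster size and reports the
fraction of epitopes that an antibody can still reach: the denser the packing,
the stronger the steric occlusion by already-bound antibodies.
"""

from nanopack.simulate import (
    AntibodyModel,
    simulate_antibody_binding,
    simulate_cluster_field,
)

model = AntibodyModel(footprint_diameter_nm=12.0, label_efficiency=1.0)
print("molecules/cluster   epitopes   bound   occupancy")
for n_mol in (10, 25, 50, 100, 200):
    field = simulate_cluster_field(
        16.0, 4.0, molecules_dist=(n_mol, n_mol), seed=5
    )
    out = simulate_antibody_binding(field, model, seed=6)
    occ = out.occupancy.mean()
    print(f"{n_mol:>17}   {out.n_molecules:>8}   {int(out.occupancy.sum()):>5}   {occ:8.3f}")
print()
print("Per-epitope occupancy falls monotonically with packing density: in a")
print("55 nm cluster a single bound antibody (12 nm footprint) occludes many")
print("neighbouring epitopes, so staining intensity under-reports tightly")
print("packed molecules relative to loosely packed ones.")
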