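"""Domain construction on a hydrogen-bonded water dimer.

Shows Boys localization, Boughton-Pulay atom lists, primary/extended domains
and the strong/distant pair classification that drive the local method.
"""
from lmp2f12 import prepare_local, rhf_reference, water_chain

mol = water_chain(2)
ref = rhf_reference(mol, "sv")
ctx = prepare_local(ref)
b = ctx.builder

print(f"{ref.n_valence} valence LMOs, {ctx.builder.core.n} core LMOs")
for i in range(ref.n_valence):
    ed = ctx.eds[i]
    print(f"LMO {i}: BPPDo atoms {b.bp_pdo(i).atoms} "
          f"(completeness {b.bp_pdo(i).completeness:.5f}); "
          f"ED atoms {ed.atoms}, {len(ed.ao_indices)} AOs, "
          f"{len(ed.occ_ids)} occupied partners")
print("\npair classification (|estimate| >= 1e-5 Eh -> strong):")
for (i, j), e in sorted(ctx.classification.estimates.items()):
    tag = "strong " if ctx.classification.is_strong(i, j) else "distant"
    print(f"  pair ({i},{j}): {e:12.3e} Eh  {tag} "
          f"[{ctx.classification.method[(i, j)]}]")
print("\nStrong pairs are treated inside extended domains; distant pairs are")
print("summed from the dipole-dipole multipole estimates above.")
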