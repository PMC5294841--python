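# Default type-signature table: family <TAB> comma-separated CRISPR-Cas types.
# The main-type signature genes are cas3 (I), cas9 (II), cas10 (III), csf1 (IV)
# and cpf1 (V); type-specific effector-module subunits are listed so that a
# locus can accumulate the three type-consistent signature genes required for
# a confident call.  This table is configuration: override it with your own
# TSV to change or extend the typing scheme (e.g. with subtype rows).
family	types
cas3	I
cas8a1	I
cas8a2	I
cas8b	I
cas8c	I
cse1	I
cse2	I
csy1	I
csy2	I
csy3	I
cas6e	I
cas6f	I
cas7	I
cas9	II
csn2	II
cas10	III
csm2	III
csm3	III
csm4	III
csm5	III
cmr1	III
cmr3	III
cmr4	III
cmr5	III
cmr6	III
csf1	IV
csf2	IV
csf3	IV
csf4	IV
cpf1	V
cas4	I,II,V
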