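# Curated registry of additional internal transcribed spacer (ITS) sites in
# euglenozoan rRNA operons: 13 numbered euglenid sites (eITS) and 7 numbered
# kinetoplastid sites (kITS).
#
# Curation notes / provenance:
# * Site numbering, lineages, and the three cross-lineage shared sites
#   (eITS10/kITS5, eITS11/kITS6, eITS13/kITS7) follow the published site
#   naming for Euglena gracilis and trypanosomatids.
# * Domain split: 12 eITS and 5 kITS sites lie inside the 28S (LSU) gene,
#   consistent with the published fragment counts (13 euglenid and 6
#   kinetoplastid mature 28S-derived fragments); the remaining numbered
#   sites (eITS1, kITS1, kITS2) are spacers flanking the 5.8S gene and are
#   tagged domain=spacer so they never enter 28S fragment arithmetic.
# * Flanking helix names are SYNTHETIC placeholders on a yeast-style 28S
#   helix numbering: the per-site flanking helices are secondary-structure
#   curation not printed in machine-readable form, so the names below fix
#   plausible, internally consistent region ids (shared sites share their
#   region id exactly).  Replace this file to run against a curated map.
#
# site_id	lineage	left_anchor	right_anchor	domain
eITS1	euglenid	F2	F3	spacer
eITS2	euglenid	H12	H13	LSU
eITS3	euglenid	H18	H19	LSU
eITS4	euglenid	H25	H26	LSU
eITS5	euglenid	H30	H31	LSU
eITS6	euglenid	H34	H35	LSU
eITS7	euglenid	H38	H39	LSU
eITS8	euglenid	H45	H46	LSU
eITS9	euglenid	H52	H53	LSU
eITS10	euglenid	H54	H55	LSU
eITS11	euglenid	H58	H59	LSU
eITS12	euglenid	H63	H64	LSU
eITS13	euglenid	H79	H80	LSU
kITS1	kinetoplastid	F1	F2	spacer
kITS2	kinetoplastid	F3	F4	spacer
kITS3	kinetoplastid	H21	H22	LSU
kITS4	kinetoplastid	H42	H43	LSU
kITS5	kinetoplastid	H54	H55	LSU
kITS6	kinetoplastid	H58	H59	LSU
kITS7	kinetoplastid	H79	H80	LSU
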