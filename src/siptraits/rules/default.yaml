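# Genomic-feature classification rules.
#
# Product-name terms are matched case-insensitively by substring containment
# after collapsing whitespace (set case_sensitive: true to switch).  Adhesion
# uses exact product-name membership by default; the "terms" variant used for
# externally annotated genome collections matches the substrings "adhesion"
# or "adhesins" instead.
case_sensitive: false
mcp:
  terms:
    - methyl-accepting chemotaxis protein
transporter:
  terms:
    - transporter
    - channel
    - exchanger
    - symporter
    - antiporter
    - exporter
    - importer
    - ATPase
    - pump
  require_tm_helix: true
adhesion:
  mode: exact
  names:
    - holdfast attachment protein HfaA
    - curli production assembly/transport component CsgG/holdfast attachment protein HfaB
    - adhesin/invasin
    - fibronectin-binding autotransporter adhesin
    - surface adhesion protein
    - autotransporter adhesin
    - adhesin HecA-like repeat protein
    - ABC-type Zn2+ transport system substrate-binding protein/surface adhesin
    - large exoprotein involved in heme utilization and adhesion
    - Tfp pilus tip-associated adhesin PilY1
    - type V secretory pathway adhesin AidA
  terms:
    - adhesion
    - adhesins
transcription_factor:
  terms:
    - transcriptional regulator
    - transcriptional repressor
    - transcriptional activator
    - transcription factor
    - transcriptional regulation
    - transcription regulator
  family_pattern: transcriptional\s+\S+\s+regulator
  use_tf_predictor: true
osmotic_stress:
  terms:
    - osmoregulated
    - osmoprotectant
    - osmotically inducible
    - osmo-dependent
    - osmolarity sensor
    - ompr
    - l-ectoine synthase
dormancy:
  terms:
    - Spo0A
    - RpfC
    - HipA
    - HipB
    - mRNA interferase MazF
    - antitoxin MazE
    - MazEF
    - RelB
    - RelE
    - RelBE
    - DinJ
    - YafQ
secreted_enzyme:
  cazy_classes:
    - GH
    - PL
    - CE
  require_signal_peptide: true
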