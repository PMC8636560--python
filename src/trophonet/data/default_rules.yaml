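# Default elimination-rule configuration for mesozooplankton gut-content
# metabarcoding. Each predator group's own taxon is removed as host signal;
# Craniata and Fungi are removed everywhere as contamination; carnivores
# additionally have the Phytoplankton macro-category removed, which expands
# to the autotroph categories listed under phytoplankton_categories.
vocabulary:
  # prey categories (family level or higher)
  - Calanoida
  - Poecilostomatoida
  - Cyclopoida
  - Dinoflagellates
  - Chlorophyta
  - Radiolaria
  - Ciliophora
  - Hydrozoa
  - Larvacea
  - Thaliacea
  - Amphipoda
  - Ostracoda
  - Euphausiacea
  - Chaetognatha
  - Gastropoda
  - Polychaeta
  - Unclassified
  # host (predator family/group) categories
  - Acartiidae
  - Aetididae
  - Calanidae
  - Candaciidae
  - Clausocalanidae
  - Eucalanidae
  - Euchaetidae
  - Metridinidae
  - Paracalanidae
  - Scolecitrichidae
  - Temoridae
  - Oithonidae
  - Oncaeidae
  # contaminants
  - Craniata
  - Fungi

phytoplankton_categories:
  - Dinoflagellates
  - Chlorophyta

global:
  - Craniata
  - Fungi

groups:
  Chaetognatha:
    feeding_habit: carnivore
    eliminate: [Chaetognatha, Phytoplankton]
  Acartiidae:
    feeding_habit: omnivore
    eliminate: [Acartiidae]
  Aetididae:
    feeding_habit: omnivore
    eliminate: [Aetididae]
  Calanidae:
    feeding_habit: omnivore
    eliminate: [Calanidae]
  Candaciidae:
    feeding_habit: carnivore
    eliminate: [Candaciidae, Phytoplankton]
  Clausocalanidae:
    feeding_habit: omnivore
    eliminate: [Clausocalanidae]
  Eucalanidae:
    feeding_habit: omnivore
    eliminate: [Eucalanidae]
  Euchaetidae:
    feeding_habit: carnivore
    eliminate: [Euchaetidae, Phytoplankton]
  Metridinidae:
    feeding_habit: omnivore
    eliminate: [Metridinidae]
  Paracalanidae:
    feeding_habit: omnivore
    eliminate: [Paracalanidae]
  Scolecitrichidae:
    feeding_habit: omnivore
    eliminate: [Scolecitrichidae]
  Temoridae:
    feeding_habit: omnivore
    eliminate: [Temoridae]
  Oithonidae:
    feeding_habit: omnivore
    eliminate: [Oithonidae]
  Oncaeidae:
    feeding_habit: omnivore
    eliminate: [Oncaeidae]
  Gastropoda:
    feeding_habit: omnivore
    eliminate: [Gastropoda]
  Hydrozoa:
    feeding_habit: carnivore
    eliminate: [Hydrozoa, Phytoplankton]
  Larvacea:
    feeding_habit: omnivore
    eliminate: [Larvacea]
  Amphipoda:
    feeding_habit: carnivore
    eliminate: [Amphipoda, Phytoplankton]
  Euphausiacea:
    feeding_habit: omnivore
    eliminate: [Euphausiacea]
  Ostracoda:
    feeding_habit: omnivore
    eliminate: [Ostracoda]
  Polychaeta:
    feeding_habit: omnivore
    eliminate: [Polychaeta]
  Thaliacea:
    feeding_habit: omnivore
    eliminate: [Thaliacea]

# Broad ecological class of each node label, used to attribute trophic-network
# nodes. Labels not listed default to other_metazoan.
node_classes:
  Calanoida: crustacean
  Poecilostomatoida: crustacean
  Cyclopoida: crustacean
  Amphipoda: crustacean
  Ostracoda: crustacean
  Euphausiacea: crustacean
  Acartiidae: crustacean
  Aetididae: crustacean
  Calanidae: crustacean
  Candaciidae: crustacean
  Clausocalanidae: crustacean
  Eucalanidae: crustacean
  Euchaetidae: crustacean
  Metridinidae: crustacean
  Paracalanidae: crustacean
  Scolecitrichidae: crustacean
  Temoridae: crustacean
  Oithonidae: crustacean
  Oncaeidae: crustacean
  Hydrozoa: gelatinous
  Larvacea: gelatinous
  Thaliacea: gelatinous
  Dinoflagellates: autotroph
  Chlorophyta: autotroph
  Radiolaria: protozoan
  Ciliophora: protozoan
  Chaetognatha: other_metazoan
  Gastropoda: other_metazoan
  Polychaeta: other_metazoan
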