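term,category
herbivore,herbivore
herbivorous,herbivore
grazer,herbivore
browser,herbivore
folivore,herbivore
granivore,herbivore
frugivore,herbivore
nectarivore,herbivore
grass,herbivore
leaves,herbivore
seeds,herbivore
fruit,herbivore
algae,herbivore
plants,herbivore
plant,herbivore
carnivore,carnivore
carnivorous,carnivore
predator,carnivore
vertebrates,carnivore
small mammals,carnivore
birds,carnivore
amphibians,carnivore
reptiles,carnivore
rodents,carnivore
meat,carnivore
insectivore,insectivore
insectivorous,insectivore
insects,insectivore
insect,insectivore
ants,insectivore
beetles,insectivore
flies,insectivore
arthropods,insectivore
invertebrates,insectivore
larvae,insectivore
piscivore,piscivore
piscivorous,piscivore
fish,piscivore
fishes,piscivore
omnivore,omnivore
omnivorous,omnivore
opportunistic,omnivore
detritivore,detritivore
detritus,detritivore
decomposer,detritivore
saprophagous,detritivore
sediment,detritivore
planktivore,planktivore
plankton,planktivore
zooplankton,planktivore
phytoplankton,planktivore
filter feeder,planktivore
scavenger,scavenger
carrion,scavenger
carcasses,scavenger
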