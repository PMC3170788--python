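# Default 90-term caption vocabulary for modality classification.
# Reconstructed list of modality-indicative terms (modality names, acronyms
# and common caption words); replace with your own file to customize.
ct
computed
tomography
mr
mri
magnetic
resonance
t1
t2
flair
gadolinium
axial
coronal
sagittal
pet
positron
emission
fdg
uptake
nm
nuclear
scintigraphy
spect
technetium
tracer
us
ultrasound
sonogram
doppler
transducer
echogenic
xr
xray
radiograph
radiographic
chest
lateral
anteroposterior
fracture
gx
graph
chart
diagram
plot
curve
histogram
schematic
drawing
illustration
table
px
photograph
photo
endoscopy
endoscopic
gross
specimen
skin
lesion
micrograph
microscopy
histology
stain
contrast
enhanced
weighted
slice
scan
imaging
angiogram
angiography
mammogram
fluoroscopy
urethrogram
barium
bone
brain
abdomen
pelvis
spine
lung
liver
cardiac
kidney
tumor
mass
cyst
artery
vein
biopsy
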