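id	label	parent	category	domain	iri
opbx:DynamicalEntity	Dynamical entity	-	entity	-	-
opbx:DynamicalProcess	Dynamical process	-	process	-	-
opbx:EnergyFlowProcess	Energy flow process	opbx:DynamicalProcess	process	-	-
opbx:ModulationProcess	Modulation process	opbx:DynamicalProcess	process	-	-
opbx:PropertyDependency	Property dependency	-	dependency	-	-
domx:fluid	Fluid domain	-	domain	-	-
domx:chemical	Chemical domain	-	domain	-	-
domx:electrical	Electrical domain	-	domain	-	-
domx:diffusion	Diffusion domain	-	domain	-	-
opbx:PhysicalProperty	Physical property	-	property	-	-
opbx:ForceProperty	Force property	opbx:PhysicalProperty	property	-	-
opbx:AmountProperty	Amount property	opbx:PhysicalProperty	property	-	-
opbx:DynamicalFlowRate	Dynamical flow rate	opbx:PhysicalProperty	property	-	-
opbx:FluidPressure	Fluid pressure	opbx:ForceProperty	property	domx:fluid	-
opbx:FluidVolume	Fluid volume	opbx:AmountProperty	property	domx:fluid	-
opbx:FluidFlowRate	Fluid flow rate	opbx:DynamicalFlowRate	property	domx:fluid	-
opbx:ChemicalConcentration	Chemical concentration	opbx:AmountProperty	property	domx:chemical	-
opbx:ChemicalAmount	Chemical molar amount	opbx:AmountProperty	property	domx:chemical	-
opbx:ChemicalFlowRate	Chemical molar flow rate	opbx:DynamicalFlowRate	property	domx:chemical	-
opbx:Voltage	Voltage	opbx:ForceProperty	property	domx:electrical	-
opbx:ChargeAmount	Charge amount	opbx:AmountProperty	property	domx:electrical	-
opbx:ChargeFlowRate	Charge flow rate	opbx:DynamicalFlowRate	property	domx:electrical	-
opbx:DiffusionalFlowRate	Diffusional flow rate	opbx:DynamicalFlowRate	property	domx:diffusion	-
opbx:EnzymeActivity	Enzyme catalytic activity	opbx:PhysicalProperty	property	-	-
fmax:AnatomicalEntity	Anatomical entity	opbx:DynamicalEntity	entity	-	-
fmax:PortionOfBlood	Portion of blood	fmax:AnatomicalEntity	entity	-	-
fmax:LeftVentricle	Left ventricle	fmax:AnatomicalEntity	entity	-	-
fmax:Aorta	Aorta	fmax:AnatomicalEntity	entity	-	-
fmax:Cytosol	Cytosol	fmax:AnatomicalEntity	entity	-	-
chebix:MolecularEntity	Molecular entity	opbx:DynamicalEntity	entity	-	-
chebix:Glucose	Glucose	chebix:MolecularEntity	entity	-	http://identifiers.org/CHEBI:17234
chebix:Glucose6Phosphate	Glucose 6-phosphate	chebix:MolecularEntity	entity	-	-
chebix:Fructose6Phosphate	Fructose 6-phosphate	chebix:MolecularEntity	entity	-	-
chebix:Fructose16Bisphosphate	Fructose 1,6-bisphosphate	chebix:MolecularEntity	entity	-	-
chebix:Phosphoenolpyruvate	Phosphoenolpyruvate	chebix:MolecularEntity	entity	-	-
chebix:Pyruvate	Pyruvate	chebix:MolecularEntity	entity	-	http://identifiers.org/CHEBI:15361
chebix:AMP	Adenosine monophosphate	chebix:MolecularEntity	entity	-	http://identifiers.org/CHEBI:16027
chebix:ATP	Adenosine triphosphate	chebix:MolecularEntity	entity	-	http://identifiers.org/CHEBI:15422
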