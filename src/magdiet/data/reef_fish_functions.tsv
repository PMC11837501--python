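mag_id	family	diet	substrates	energy	vitamins	benefits
H1N1.001	Vibrionaceae	piscivorous	proteins;starch	glycolysis;pyruvate_oxidation;tca_cycle;nitrate_reduction;formate_fermentation;acetogenesis	B1;B2;B7;B9;B12	protein_degradation;vitamin_production
H1N1.003	Alcanivoracaceae	piscivorous	proteins;fatty_acids	glycolysis;pyruvate_oxidation;tca_cycle;beta_oxidation;acetogenesis(p)	B2;B7;B9;B12	protein_degradation;vitamin_production
H1N1.005	Phaeomarinobacteraceae	piscivorous	collagen;proteins;cellulose	glycolysis;tca_cycle(p);pyruvate_oxidation	B7	vitamin_production
H1N1.006	Rhodobacteraceae	piscivorous	proteins;fatty_acids	glycolysis;pyruvate_oxidation;tca_cycle(p);beta_oxidation;acetogenesis	B7;B9;B12	protein_degradation;vitamin_production
H1N1.007	Thalassospiraceae	piscivorous	proteins;fatty_acids	glycolysis;pyruvate_oxidation;tca_cycle;beta_oxidation;lactate_fermentation;acetogenesis(p)	B1;B9;B12	protein_degradation;vitamin_production
H1N1.009	Cyclobacteriaceae	piscivorous	proteins;cellulose;starch;chitin	glycolysis;pyruvate_oxidation;tca_cycle(p);acetogenesis(p)	B7;B9	protein_degradation;vitamin_production
H1N1.010	Vibrionaceae	piscivorous	proteins;starch	pyruvate_oxidation;tca_cycle(p);nitrate_reduction;acetogenesis;formate_fermentation	B1;B7;B9;B12	protein_degradation;vitamin_production
H1N1.011	GCA-2718715	piscivorous	cellulose	glycolysis(p);lactate_fermentation;acetogenesis(p)
H1N1.012	Rhodobacteraceae	piscivorous	proteins;fatty_acids	glycolysis;pyruvate_oxidation;tca_cycle(p);beta_oxidation;nitrate_reduction;acetogenesis	B7;B9;B12	protein_degradation;vitamin_production
H1N1.015	Cyclobacteriaceae	piscivorous	fatty_acids	glycolysis;pyruvate_oxidation;tca_cycle(p);beta_oxidation;acetogenesis(p)	B7;B9	vitamin_production
H1N1.018	Minwuiaceae	piscivorous	proteins;fatty_acids	glycolysis;pyruvate_oxidation;tca_cycle;beta_oxidation;acetogenesis(p)	B12	protein_degradation;vitamin_production
H1N1.021	Porticoccaceae	piscivorous	proteins	glycolysis(p);pyruvate_oxidation;acetogenesis(p)	B9	protein_degradation;vitamin_production
H1N1.022	Alteromonadaceae	piscivorous	proteins;fatty_acids;cellulose;hemicellulose;starch	glycolysis;pyruvate_oxidation;tca_cycle;beta_oxidation;acetogenesis(p)	B1;B2;B7;B9	protein_degradation;vitamin_production
H1N1.025	Alteromonadaceae	piscivorous	proteins;starch	glycolysis;pyruvate_oxidation;acetogenesis	B2;B9	protein_degradation;vitamin_production
H1N1.026	Sphingomonadaceae	piscivorous	proteins	glycolysis;pyruvate_oxidation;tca_cycle(p);acetogenesis(p)	B1;B7	protein_degradation;vitamin_production
H1N1.028	Maricaulaceae	piscivorous	proteins;cellulose	glycolysis(p);pyruvate_oxidation;acetogenesis(p)	B1;B7;B9	protein_degradation;vitamin_production
H1N1.030	Flammeovirgaceae	piscivorous	proteins;fatty_acids;cellulose;hemicellulose;starch;chitin	glycolysis;pyruvate_oxidation;tca_cycle(p);beta_oxidation;acetogenesis	B1;B7;B9	protein_degradation;vitamin_production
H1N1.033	GCA-2696645	piscivorous	proteins;cellulose	glycolysis(p);pyruvate_oxidation;tca_cycle(p);acetogenesis(p)		protein_degradation
T4LTN.001	Bacteroidaceae	herbivorous	cellulose;hemicellulose;starch;proteins;chitin	glycolysis;pyruvate_oxidation;tca_cycle(p);h2_fermentation;acetogenesis(p)	B1;B2;B7;B9	plant_matter_degradation;vitamin_production
T4LTN.002	Paludibacteraceae	herbivorous	cellulose;proteins	glycolysis;pyruvate_oxidation;acetogenesis(p)		plant_matter_degradation
T4LTN.003	Vibrionaceae	herbivorous	starch;proteins;fatty_acids;chitin	glycolysis;pyruvate_oxidation;tca_cycle(p);nitrate_reduction;acetogenesis;formate_fermentation;beta_oxidation	B1;B2;B7;B9	plant_matter_degradation;vitamin_production
T4LTN.004	Shewanellaceae	herbivorous	starch;proteins;fatty_acids	glycolysis;pyruvate_oxidation;tca_cycle;nitrate_reduction;acetogenesis;formate_fermentation;beta_oxidation	B1;B2;B7;B9;B12	plant_matter_degradation;vitamin_production
T4LTN.005	Tannerellaceae	herbivorous	cellulose;hemicellulose;starch;proteins;chitin	glycolysis;pyruvate_oxidation;tca_cycle(p);h2_fermentation;acetogenesis(p)	B1;B2;B7;B9;B12	plant_matter_degradation;vitamin_production
T4LTN.006	Lachnospiraceae	herbivorous	cellulose;hemicellulose;starch;proteins;chitin	glycolysis;pyruvate_oxidation;lactate_fermentation;h2_fermentation;acetogenesis(p)	B7;B12	plant_matter_degradation;vitamin_production
T4LTN.007	Alteromonadaceae	herbivorous	cellulose;hemicellulose;starch	glycolysis;pyruvate_oxidation;tca_cycle(p);nitrate_reduction;acetogenesis	B1;B2;B7;B9	plant_matter_degradation;vitamin_production
T4LTN.009	Alteromonadaceae	herbivorous	cellulose;starch	glycolysis;pyruvate_oxidation;tca_cycle(p);acetogenesis	B1;B7	plant_matter_degradation;vitamin_production
T4LTN.010	Sphaerochaetaceae	herbivorous	proteins	glycolysis;pyruvate_oxidation;h2_fermentation;acetogenesis(p)
T4LTN.011	UBA1402	herbivorous	hemicellulose	glycolysis;pyruvate_oxidation;tca_cycle(p);acetogenesis(p)	B9	plant_matter_degradation;vitamin_production
T4LTN.012	Vibrionaceae	herbivorous	starch;proteins;fatty_acids	glycolysis;pyruvate_oxidation;tca_cycle;nitrate_reduction;acetogenesis;formate_fermentation;beta_oxidation	B1;B2;B7;B9;B12	plant_matter_degradation;vitamin_production
T4LTN.014.2	CAG-822	herbivorous	starch	glycolysis(p);pyruvate_oxidation;acetogenesis(p)		plant_matter_degradation
T4LTN.014.3	UBA6164	herbivorous	simple_saccharides
T4LTN.015	Ruminococcaceae	herbivorous	cellulose;hemicellulose;chitin	glycolysis;pyruvate_oxidation;h2_fermentation;acetogenesis(p)		plant_matter_degradation
T4LTN.016	Saccharospirillaceae	herbivorous	cellulose;proteins;fatty_acids	pyruvate_oxidation;nitrate_reduction;acetogenesis;beta_oxidation	B1;B7;B9	plant_matter_degradation;vitamin_production
T4LTN.017	Ruminococcaceae	herbivorous	simple_saccharides	glycolysis;pyruvate_oxidation;h2_fermentation;acetogenesis(p)	B7	vitamin_production
T4LTN.022	Sphingomonadaceae	herbivorous	proteins	glycolysis;pyruvate_oxidation;tca_cycle(p);acetogenesis(p)	B1	vitamin_production
T4LTN.023	P3	herbivorous	proteins	glycolysis;pyruvate_oxidation;h2_fermentation;acetogenesis(p)	B1	vitamin_production
Tr3LTN.002	Shewanellaceae	invertivorous	proteins;fatty_acids	glycolysis;pyruvate_oxidation;tca_cycle;nitrate_reduction;acetogenesis;formate_fermentation;beta_oxidation	B1;B2;B7;B9;B12	protein_degradation;vitamin_production
Tr3LTN.005	Rhodobacteraceae	invertivorous	proteins;fatty_acids	glycolysis;pyruvate_oxidation;tca_cycle(p);beta_oxidation	B2;B9;B12	protein_degradation;vitamin_production
Tr3LTN.006	Cellvibrionaceae	invertivorous	proteins;fatty_acids	glycolysis;pyruvate_oxidation;beta_oxidation	B1;B7;B9	protein_degradation;vitamin_production
Tr3LTN.008	Arcobacteraceae	invertivorous	simple_saccharides	glycolysis;pyruvate_oxidation;tca_cycle(p)	B1;B7	vitamin_production
Tr3LTN.016	Bacilli	invertivorous	simple_saccharides	glycolysis;pyruvate_oxidation;h2_fermentation
Tr3LTN.017	UBA12223	invertivorous	simple_saccharides	glycolysis(p);pyruvate_oxidation;tca_cycle(p)
Tr3LTN.026	Bacteriovoracaceae	invertivorous	simple_saccharides	glycolysis(p);pyruvate_oxidation
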